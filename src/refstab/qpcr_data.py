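"""Data model and I/O for wide-format qPCR measurement matrices.

Matrices are stored assays x samples. Two value kinds are supported:

* ``cq`` — raw quantification cycles (PCR cycles); may contain empty cells
  while technical replicate wells are still unaveraged.
* ``quantity`` — linear-scale relative quantities (strictly positive).

File format: delimited text, row 1 is a header whose first field is ignored
and whose remaining fields are sample (or well) ids; column 1 holds assay
ids; cells are plain numbers with "." as decimal point.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    FixtureIntegrityError,
    MatrixFormatError,
    MatrixParseError,
    ValidationError,
)

__all__ = [
    "CqMatrix",
    "QuantityMatrix",
    "MValueTable",
    "read_matrix",
    "write_matrix",
    "average_replicates",
    "cq_to_quantity",
    "load_table1_fixture",
    "table_to_ranked_lists",
    "TABLE1_ASSAYS",
    "TABLE1_EXPERIMENTS",
]

# Printed column order of the packaged 19 x 11 M-value table; also the
# default tie-break order when sorting a table row into a ranked list.
TABLE1_ASSAYS = (
    "Alu-Sq", "TBP", "HPRT1", "YWHAZ", "GAPDH",
    "SDHA", "HMBS", "B2M", "UBC", "ACTB", "RPL13A",
)
TABLE1_EXPERIMENTS = tuple("ABCDEFGHIJKLMNOPQRS")

_TABLE1_TSV_SHA256 = "f916a33972db8b9f01710d32134ce13499a0434a85d27270d75daaa554d241ae"
_TABLE1_META_SHA256 = "ca283e8984b56e75f5b6c52e5c391c6d995d8122cbab1a631da6b4755d3d2661"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise MatrixFormatError(f"duplicate {kind} id: {name!r}")
        seen.add(name)


@dataclass
class CqMatrix:
    """Quantification-cycle matrix with per-assay amplification efficiencies.

    ``efficiency`` is the fold amplification per cycle E with 1 < E <= 2
    (scalar broadcast to all assays, or one value per assay).
    ``replicate_groups`` optionally maps raw well ids (the columns) to sample
    ids; while it is set, empty (NaN) cells are permitted.
    """

    assay_ids: list[str]
    sample_ids: list[str]
    cq: np.ndarray
    efficiency: np.ndarray | float = 2.0
    replicate_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.assay_ids = list(self.assay_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.sample_ids, "sample/well")
        self.cq = np.array(self.cq, dtype=float)
        if self.cq.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise ValidationError(
                f"cq shape {self.cq.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.sample_ids)} samples"
            )
        eff = np.broadcast_to(
            np.asarray(self.efficiency, dtype=float), (len(self.assay_ids),)
        ).copy()
        if not np.all(np.isfinite(eff)) or not np.all((eff > 1.0) & (eff <= 2.0)):
            raise ValidationError("amplification efficiency must satisfy 1 < E <= 2")
        self.efficiency = eff
        if self.replicate_groups is None:
            if not np.all(np.isfinite(self.cq)):
                bad = np.argwhere(~np.isfinite(self.cq))[0]
                raise MatrixFormatError(
                    "missing Cq value at assay "
                    f"{self.assay_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r} "
                    "(empty cells require replicate_groups)"
                )
        else:
            unknown = set(self.replicate_groups) - set(self.sample_ids)
            if unknown:
                raise ValidationError(
                    f"replicate_groups references unknown wells: {sorted(unknown)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cq.shape


@dataclass
class QuantityMatrix:
    """Relative-quantity matrix (linear scale, strictly positive)."""

    assay_ids: list[str]
    sample_ids: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.assay_ids = list(self.assay_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.sample_ids, "sample")
        self.q = np.array(self.q, dtype=float)
        if self.q.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise ValidationError(
                f"q shape {self.q.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.q)) or not np.all(self.q > 0):
            raise ValidationError("relative quantities must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.q.shape

    def assay_index(self, assay: str) -> int:
        try:
            return self.assay_ids.index(assay)
        except ValueError:
            raise ValidationError(f"unknown assay: {assay!r}") from None


@dataclass
class MValueTable:
    """Experiments x assays table of stability M-values (complete, >= 0)."""

    experiment_ids: list[str]
    assay_ids: list[str]
    m: np.ndarray
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.experiment_ids = list(self.experiment_ids)
        self.assay_ids = list(self.assay_ids)
        _check_unique(self.experiment_ids, "experiment")
        _check_unique(self.assay_ids, "assay")
        self.m = np.array(self.m, dtype=float)
        if self.m.shape != (len(self.experiment_ids), len(self.assay_ids)):
            raise ValidationError("m shape does not match experiment/assay ids")
        if not np.all(np.isfinite(self.m)) or np.any(self.m < 0):
            raise ValidationError("M-values must be finite and >= 0")

    def value(self, experiment: str, assay: str) -> float:
        return float(
            self.m[self.experiment_ids.index(experiment), self.assay_ids.index(assay)]
        )


def _parse_wide(
    text: str, delimiter: str, source: str
) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a wide matrix; empty cells become NaN."""
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise MatrixFormatError(f"{source}: need a header row and at least one data row")
    sample_ids = [c.strip() for c in rows[0][1:]]
    assay_ids: list[str] = []
    values = np.full((len(rows) - 1, len(sample_ids)), np.nan)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(sample_ids) + 1:
            raise MatrixFormatError(
                f"{source}: row {i + 1} has {len(row)} fields, expected {len(sample_ids) + 1}"
            )
        assay_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                values[i - 1, j] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{source}: non-numeric cell {cell!r} at row {i + 1} "
                    f"(assay {row[0].strip()!r}), column {j + 2} "
                    f"(sample {sample_ids[j]!r})"
                ) from None
    _check_unique(assay_ids, "assay")
    _check_unique(sample_ids, "sample/well")
    return assay_ids, sample_ids, values


def read_matrix(
    path: str | Path,
    value_kind: str = "quantity",
    delimiter: str | None = None,
    efficiency: np.ndarray | float = 2.0,
    replicate_groups: dict[str, str] | None = None,
) -> CqMatrix | QuantityMatrix:
    """Read a wide-format matrix file.

    ``delimiter`` defaults by extension: "," for ``.csv``, tab otherwise.
    Empty cells are only legal for ``value_kind="cq"`` together with
    ``replicate_groups`` (raw wells awaiting replicate averaging).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    assay_ids, sample_ids, values = _parse_wide(
        path.read_text(encoding="utf-8"), delimiter, str(path)
    )
    if value_kind == "quantity":
        if np.any(np.isnan(values)):
            bad = np.argwhere(np.isnan(values))[0]
            raise MatrixFormatError(
                f"{path}: empty quantity cell at assay {assay_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        return QuantityMatrix(assay_ids, sample_ids, values)
    if value_kind == "cq":
        if replicate_groups is None and np.any(np.isnan(values)):
            bad = np.argwhere(np.isnan(values))[0]
            raise MatrixFormatError(
                f"{path}: empty Cq cell at assay {assay_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r} (empty cells require replicate_groups)"
            )
        return CqMatrix(
            assay_ids, sample_ids, values,
            efficiency=efficiency, replicate_groups=replicate_groups,
        )
    raise ValidationError(f"value_kind must be 'cq' or 'quantity', got {value_kind!r}")


def write_matrix(
    m: CqMatrix | QuantityMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix in the wide format, values at 6 significant digits."""
    values = m.cq if isinstance(m, CqMatrix) else m.q
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["assay", *m.sample_ids])
        for name, row in zip(m.assay_ids, values):
            writer.writerow([name] + ["" if math.isnan(v) else f"{v:.6g}" for v in row])


def average_replicates(m: CqMatrix) -> CqMatrix:
    """Collapse raw wells to samples by arithmetic mean on the Cq scale.

    Missing wells are ignored; a (assay, sample) pair with no surviving well
    is a completeness error. Sample order follows first appearance of each
    sample id among the wells.
    """
    if m.replicate_groups is None:
        raise ValidationError("average_replicates requires replicate_groups")
    sample_order: list[str] = []
    wells_of: dict[str, list[int]] = {}
    for j, well in enumerate(m.sample_ids):
        sample = m.replicate_groups.get(well, well)
        if sample not in wells_of:
            wells_of[sample] = []
            sample_order.append(sample)
        wells_of[sample].append(j)
    out = np.empty((len(m.assay_ids), len(sample_order)))
    for s, sample in enumerate(sample_order):
        block = m.cq[:, wells_of[sample]]
        counts = np.sum(~np.isnan(block), axis=1)
        if np.any(counts == 0):
            g = int(np.argmax(counts == 0))
            raise MatrixFormatError(
                f"no replicate wells for assay {m.assay_ids[g]!r}, sample {sample!r}"
            )
        out[:, s] = np.nanmean(block, axis=1)
    return CqMatrix(m.assay_ids, sample_order, out, efficiency=m.efficiency)


def cq_to_quantity(m: CqMatrix) -> QuantityMatrix:
    """Efficiency-corrected Cq -> relative quantity transform.

    q[g, s] = E_g ** (min_s' cq[g, s'] - cq[g, s]); the per-assay maximum
    quantity is therefore exactly 1 (scaling convention; all downstream
    stability statistics are invariant to per-assay scaling).
    """
    if m.replicate_groups is not None:
        m = average_replicates(m)
    delta = m.cq.min(axis=1, keepdims=True) - m.cq
    q = np.asarray(m.efficiency)[:, None] ** delta
    return QuantityMatrix(m.assay_ids, m.sample_ids, q)


def _packaged_text(name: str, expected_sha256: str) -> str:
    data = resources.files("refstab.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha256:
        raise FixtureIntegrityError(
            f"packaged resource {name} is corrupted (sha256 {digest})"
        )
    return data.decode("utf-8")


def load_table1_fixture() -> MValueTable:
    """Load the packaged 19-experiment x 11-assay M-value table.

    Experiments are labelled A-S; per-experiment descriptions (treatment and
    cell lines) are attached as metadata strings. The resource is verified
    against a recorded checksum before parsing.
    """
    text = _packaged_text("table1_m_values.tsv", _TABLE1_TSV_SHA256)
    meta = json.loads(_packaged_text("table1_experiments.json", _TABLE1_META_SHA256))
    experiment_ids, assay_ids, values = _parse_wide(text, "\t", "table1_m_values.tsv")
    table = MValueTable(experiment_ids, assay_ids, values, descriptions=dict(meta))
    if (
        tuple(table.experiment_ids) != TABLE1_EXPERIMENTS
        or tuple(table.assay_ids) != TABLE1_ASSAYS
        or np.any(np.isnan(table.m))
    ):
        raise FixtureIntegrityError("packaged M-value table has unexpected layout")
    return table


def table_to_ranked_lists(t: MValueTable, tie_rule: str = "column_order"):
    """Turn each table row into a ranked list (ascending M = most stable first).

    ``tie_rule`` controls equal-M ordering: ``column_order`` (default) keeps
    the table's printed column order, ``assay_id`` sorts ties alphabetically.
    Per-assay weights are the raw M-values.
    """
    from .rank_aggregation import RankedList  # local import: avoids cycle

    if tie_rule not in ("column_order", "assay_id"):
        raise ValidationError(f"unknown tie_rule: {tie_rule!r}")
    lists = []
    for i, exp in enumerate(t.experiment_ids):
        row = t.m[i]
        if tie_rule == "column_order":
            order = np.argsort(row, kind="stable")
        else:
            order = sorted(range(len(row)), key=lambda j: (row[j], t.assay_ids[j]))
        lists.append(
            RankedList(
                experiment_id=exp,
                assays=[t.assay_ids[j] for j in order],
                weights=row[list(order)],
            )
        )
    return lists
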