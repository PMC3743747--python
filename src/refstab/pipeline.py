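"""End-to-end orchestration and the command-line interface.

Stages: per-experiment stability analysis (M-values, stepwise ranking,
V-curve) -> cross-experiment consensus ranking. Reports are written in two
forms: a machine-readable JSON record and a human-readable text rendering,
with real numbers serialized at 6 significant digits.

Exit codes: 0 success, 2 validation/format error, 3 I/O error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import click
import numpy as np
import yaml

from . import __version__
from .errors import RefstabError, ValidationError
from .genorm import DEFAULT_V_CUTOFF, NfCurve, StabilityResult, rank_stepwise, v_curve
from .qpcr_data import (
    CqMatrix,
    MValueTable,
    QuantityMatrix,
    cq_to_quantity,
    load_table1_fixture,
    read_matrix,
)
from .rank_aggregation import (
    AggregationResult,
    CEParams,
    RankedList,
    aggregate_table1,
    borda_aggregate,
    brute_force_aggregate,
    ce_aggregate,
    normalize_weights,
)
from .synthetic_data import SimConfig, simulate, write_dataset

log = logging.getLogger("refstab")

_RUN_CONFIG_KEYS = {
    "inputs", "value_kind", "efficiency", "v_cutoff", "method",
    "seed", "n_samples_per_iter", "elite_fraction", "smoothing",
    "convergence_patience", "max_iters", "out_dir", "verbosity",
}


@dataclass
class RunConfig:
    """Flat pipeline configuration (mirrors the config-file key set)."""

    inputs: list[str] = field(default_factory=list)
    value_kind: str = "quantity"
    efficiency: float = 2.0
    v_cutoff: float = DEFAULT_V_CUTOFF
    method: str = "ce"
    seed: int = 0
    n_samples_per_iter: int | None = None
    elite_fraction: float = 0.1
    smoothing: float = 0.25
    convergence_patience: int = 5
    max_iters: int = 1000
    out_dir: str | None = None
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.v_cutoff <= 0:
            raise ValidationError("v_cutoff must be > 0")
        for p in self.inputs:
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")

    def ce_params(self) -> CEParams:
        return CEParams(
            n_samples_per_iter=self.n_samples_per_iter,
            elite_fraction=self.elite_fraction,
            smoothing=self.smoothing,
            convergence_patience=self.convergence_patience,
            max_iters=self.max_iters,
            seed=self.seed,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config file; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must hold a mapping")
    unknown = set(raw) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stability_record(
    label: str, result: StabilityResult, curve: NfCurve
) -> dict:
    """Machine-readable stability report for one experiment."""
    return {
        "experiment": label,
        "assays": result.assay_ids,
        "m_values": {a: _sig6(m) for a, m in result.m_values.items()},
        "ranking": result.ranking,
        "exclusion_trace": [[a, _sig6(m)] for a, m in result.exclusion_trace],
        "final_pair_tied": result.final_pair_tied,
        "v_values": {str(n): _sig6(v) for n, v in curve.v_values.items()},
        "recommended_n": curve.recommended_n,
        "cutoff": curve.cutoff,
    }


def render_stability_text(rec: dict) -> str:
    lines = [f"Stability report — experiment {rec['experiment']}", ""]
    lines.append("assay            M (full set)   stepwise rank")
    order = {a: i + 1 for i, a in enumerate(rec["ranking"])}
    for a in sorted(rec["assays"], key=lambda a: rec["m_values"][a]):
        lines.append(f"{a:<16} {rec['m_values'][a]:<14g} {order[a]}")
    lines.append("")
    lines.append(f"V-values (cutoff {rec['cutoff']}):")
    for n, v in rec["v_values"].items():
        lines.append(f"  V_{n}/{int(n) + 1} = {v:g}")
    lines.append(f"recommended number of reference genes: {rec['recommended_n']}")
    return "\n".join(lines) + "\n"


def run_stability(
    config: RunConfig, experiment: str | Path, label: str | None = None
) -> dict:
    """Stability analysis of one experiment file; writes reports if out_dir set."""
    t0 = time.perf_counter()
    path = Path(experiment)
    label = label or path.stem
    try:
        m = read_matrix(
            path, value_kind=config.value_kind, efficiency=config.efficiency
        )
    except RefstabError as exc:
        raise type(exc)(f"experiment {label!r}: {exc}") from exc
    q = cq_to_quantity(m) if isinstance(m, CqMatrix) else m
    result = rank_stepwise(q)
    curve = v_curve(q, result, cutoff=config.v_cutoff)
    rec = stability_record(label, result, curve)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{label}.stability.json").write_text(
            json.dumps(rec, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out / f"{label}.stability.txt").write_text(
            render_stability_text(rec), encoding="utf-8"
        )
    log.info("stability[%s] done in %.3fs", label, time.perf_counter() - t0)
    return rec


def _lists_from_stability_records(records: Sequence[dict]) -> list[RankedList]:
    """Ranked lists from stability reports: assays sorted by full-set M."""
    lists = []
    for rec in records:
        assays = sorted(
            rec["assays"], key=lambda a: (float(rec["m_values"][a]), rec["assays"].index(a))
        )
        weights = np.array([float(rec["m_values"][a]) for a in assays])
        lists.append(
            RankedList(experiment_id=rec["experiment"], assays=assays, weights=weights)
        )
    return lists


def aggregation_record(result: AggregationResult) -> dict:
    return {
        "method": result.method,
        "consensus": result.consensus,
        "objective": _sig6(result.objective),
        "seed": result.seed,
        "trace": [_sig6(v) for v in result.trace],
        "per_experiment": result.per_experiment,
    }


def render_aggregation_text(rec: dict) -> str:
    lines = [f"Consensus ranking ({rec['method']}, seed {rec['seed']})", ""]
    for i, a in enumerate(rec["consensus"], start=1):
        lines.append(f"{i:>3}. {a}")
    lines.append("")
    lines.append(f"objective (total weighted footrule): {rec['objective']:g}")
    if rec["trace"]:
        lines.append(f"iterations: {len(rec['trace'])}")
    return "\n".join(lines) + "\n"


def run_aggregation(
    config: RunConfig,
    stability_records: Sequence[dict] | None = None,
    table: MValueTable | None = None,
) -> dict:
    """Consensus over stability reports or an M-value table; writes reports."""
    t0 = time.perf_counter()
    if (stability_records is None) == (table is None):
        raise ValidationError("provide either stability records or an M-value table")
    if table is not None:
        result = aggregate_table1(table, method=config.method, params=config.ce_params())
    else:
        lists = [normalize_weights(l) for l in _lists_from_stability_records(stability_records)]
        if config.method == "ce":
            result = ce_aggregate(lists, config.ce_params())
        elif config.method == "borda":
            result = borda_aggregate(lists)
        elif config.method == "brute":
            result = brute_force_aggregate(lists)
        else:
            raise ValidationError(f"unknown aggregation method: {config.method!r}")
        result.per_experiment = {l.experiment_id: list(l.assays) for l in lists}
    rec = aggregation_record(result)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "consensus.json").write_text(
            json.dumps(rec, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out / "consensus.txt").write_text(render_aggregation_text(rec), encoding="utf-8")
    log.info("aggregation done in %.3fs", time.perf_counter() - t0)
    return rec


def reproduce_table1(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """One-command consensus reproduction from the packaged M-value table.

    Runs the cross-entropy aggregation (with the Borda baseline for
    comparison) over the 19 packaged experiments and summarizes the position
    of each assay plus its mean M across experiments.
    """
    table = load_table1_fixture()
    ce = aggregate_table1(table, method="ce", params=CEParams(seed=seed))
    borda = aggregate_table1(table, method="borda")
    mean_m = {
        a: _sig6(float(np.mean(table.m[:, j])))
        for j, a in enumerate(table.assay_ids)
    }
    summary = {
        "seed": seed,
        "consensus_ce": ce.consensus,
        "objective_ce": _sig6(ce.objective),
        "consensus_borda": borda.consensus,
        "objective_borda": _sig6(borda.objective),
        "alu_position_ce": ce.consensus.index("Alu-Sq") + 1,
        "mean_m_per_assay": mean_m,
        "n_experiments": len(table.experiment_ids),
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "table1_consensus.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return summary


# ---------------------------------------------------------------------------
# CLI


def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(
        stream=sys.stderr, level=level, format="%(levelname)s %(name)s: %(message)s"
    )


def _log_run(command: str, params: dict) -> None:
    log.info(
        "%s v%s | config hash %s | %s",
        command, __version__, _config_hash(params), params,
    )


@click.group()
@click.version_option(version=__version__, prog_name="refstab")
@click.option("-v", "--verbose", count=True, help="Increase log verbosity.")
def main(verbose: int) -> None:
    """Reference-gene stability analysis and consensus ranking for RT-qPCR."""
    _setup_logging(verbose)


@main.command("simulate")
@click.option("--n-genes", type=int, default=6, show_default=True)
@click.option("--n-samples", type=int, default=20, show_default=True)
@click.option("--sigma", type=str, default="0.2", show_default=True,
              help="Per-gene noise SD: one value or comma-separated list.")
@click.option("--sigma-content", type=float, default=0.0, show_default=True)
@click.option("--perturb", type=str, multiple=True, metavar="GENE=DELTA",
              help="Treatment effect (log2) on a gene; repeatable.")
@click.option("--treated-fraction", type=float, default=0.5, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), required=True)
def simulate_cmd(n_genes, n_samples, sigma, sigma_content, perturb,
                 treated_fraction, seed, out_dir) -> None:
    """Simulate a qPCR experiment and write matrices plus a truth sidecar."""
    sigmas = [float(s) for s in sigma.split(",")]
    perturbed = {}
    for spec_ in perturb:
        gene, _, delta = spec_.partition("=")
        if not delta:
            raise ValidationError(f"--perturb expects GENE=DELTA, got {spec_!r}")
        perturbed[gene] = float(delta)
    cfg = SimConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        sigma=sigmas[0] if len(sigmas) == 1 else np.array(sigmas),
        sigma_content=sigma_content,
        perturbed=perturbed,
        treated_fraction=treated_fraction,
        seed=seed,
    )
    _log_run("simulate", {"seed": seed, "n_genes": n_genes, "n_samples": n_samples})
    write_dataset(simulate(cfg), out_dir)
    click.echo(f"wrote quantities.tsv, cq.tsv, truth.json to {out_dir}")


@main.command("stability")
@click.argument("matrix", type=click.Path(exists=True))
@click.option("--value-kind", type=click.Choice(["cq", "quantity"]),
              default="quantity", show_default=True)
@click.option("--efficiency", type=float, default=2.0, show_default=True)
@click.option("--v-cutoff", type=float, default=DEFAULT_V_CUTOFF, show_default=True)
@click.option("--out-dir", type=click.Path(), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML config file; CLI flags override it.")
def stability_cmd(matrix, value_kind, efficiency, v_cutoff, out_dir, config_path) -> None:
    """Per-experiment stability analysis (M-values, ranking, V-curve)."""
    cfg = load_run_config(config_path) if config_path else RunConfig()
    cfg = dataclasses.replace(
        cfg, value_kind=value_kind, efficiency=efficiency,
        v_cutoff=v_cutoff, out_dir=out_dir,
    )
    _log_run("stability", {"matrix": matrix, "value_kind": value_kind,
                           "efficiency": efficiency, "v_cutoff": v_cutoff})
    rec = run_stability(cfg, matrix)
    click.echo(render_stability_text(rec), nl=False)


@main.command("aggregate")
@click.argument("inputs", nargs=-1, type=click.Path(exists=True))
@click.option("--table", "table_path", type=click.Path(exists=True), default=None,
              help="Wide M-value table (experiments x assays) instead of reports.")
@click.option("--method", type=click.Choice(["borda", "ce", "brute"]),
              default="ce", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-samples-per-iter", type=int, default=None)
@click.option("--elite-fraction", type=float, default=0.1, show_default=True)
@click.option("--smoothing", type=float, default=0.25, show_default=True)
@click.option("--patience", type=int, default=5, show_default=True)
@click.option("--max-iters", type=int, default=1000, show_default=True)
@click.option("--out-dir", type=click.Path(), default=None)
def aggregate_cmd(inputs, table_path, method, seed, n_samples_per_iter,
                  elite_fraction, smoothing, patience, max_iters, out_dir) -> None:
    """Consensus over stability reports (JSON) or a wide M-value table."""
    cfg = RunConfig(
        method=method, seed=seed, n_samples_per_iter=n_samples_per_iter,
        elite_fraction=elite_fraction, smoothing=smoothing,
        convergence_patience=patience, max_iters=max_iters, out_dir=out_dir,
    )
    _log_run("aggregate", {"method": method, "seed": seed,
                           "inputs": list(inputs), "table": table_path})
    if table_path is not None:
        if inputs:
            raise ValidationError("give either report files or --table, not both")
        from .qpcr_data import _parse_wide

        exp_ids, assay_ids, values = _parse_wide(
            Path(table_path).read_text(encoding="utf-8"),
            "," if str(table_path).endswith(".csv") else "\t",
            str(table_path),
        )
        rec = run_aggregation(cfg, table=MValueTable(exp_ids, assay_ids, values))
    else:
        if not inputs:
            raise ValidationError("no stability reports given")
        records = [json.loads(Path(p).read_text(encoding="utf-8")) for p in inputs]
        rec = run_aggregation(cfg, stability_records=records)
    click.echo(render_aggregation_text(rec), nl=False)


@main.command("reproduce-table1")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(), default=None)
def reproduce_table1_cmd(seed, out_dir) -> None:
    """Consensus ranking over the packaged 19-experiment M-value table."""
    _log_run("reproduce-table1", {"seed": seed})
    summary = reproduce_table1(seed=seed, out_dir=out_dir)
    click.echo("Consensus (cross-entropy): " + " > ".join(summary["consensus_ce"]))
    click.echo("Consensus (Borda):         " + " > ".join(summary["consensus_borda"]))
    click.echo(f"Alu-Sq consensus position: {summary['alu_position_ce']}")
    click.echo(f"objective CE/Borda: {summary['objective_ce']:g} / "
               f"{summary['objective_borda']:g}")
    click.echo("mean M across experiments:")
    for a, m in sorted(summary["mean_m_per_assay"].items(), key=lambda kv: kv[1]):
        click.echo(f"  {a:<8} {m:g}")


@main.command("version")
def version_cmd() -> None:
    """Print the tool version."""
    click.echo(__version__)


def cli_entry() -> None:  # pragma: no cover - thin wrapper
    try:
        main(standalone_mode=False)
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        sys.exit(exc.exit_code)
    except click.Abort:
        sys.exit(1)
    except RefstabError as exc:
        print(f"error: {exc}", file=sys.stderr)
        sys.exit(2)
    except OSError as exc:
        print(f"i/o error: {exc}", file=sys.stderr)
        sys.exit(3)
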