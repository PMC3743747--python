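"""Synthetic qPCR data with known ground-truth stability structure.

Generative model (all noise in log2 units):

    log2 x[g, s] = log2 mu_g + c_s + delta_g * 1[s treated] + eps_gs

with c_s ~ Normal(0, sigma_content^2) shared by all genes within a sample
(global mRNA-content factor) and eps_gs ~ Normal(0, sigma_g^2) independent
(gene stability noise). Under this model the expected stability measure has
the closed form M_j = mean_{k != j} sqrt(sigma_j^2 + sigma_k^2), which makes
every analysis stage testable without external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .qpcr_data import CqMatrix, QuantityMatrix, write_matrix

__all__ = ["SimConfig", "SyntheticDataset", "simulate", "expected_m",
           "simulate_experiment_suite", "write_dataset"]


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    ``mu``/``sigma`` broadcast from scalars to per-gene vectors. ``perturbed``
    maps gene id -> treatment effect delta (log2 fold-change) applied to the
    first round(treated_fraction * n_samples) samples.
    """

    n_genes: int
    n_samples: int
    mu: float | np.ndarray = 100.0
    sigma: float | np.ndarray = 0.2
    sigma_content: float = 0.0
    perturbed: dict[str, float] = field(default_factory=dict)
    treated_fraction: float = 0.5
    seed: int = 0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValidationError("need at least 2 genes and 2 samples")
        self.mu = np.broadcast_to(
            np.asarray(self.mu, dtype=float), (self.n_genes,)
        ).copy()
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), (self.n_genes,)
        ).copy()
        if np.any(self.mu <= 0):
            raise ValidationError("mu must be > 0")
        if np.any(self.sigma < 0) or self.sigma_content < 0:
            raise ValidationError("sigma values must be >= 0")
        if not 0.0 <= self.treated_fraction <= 1.0:
            raise ValidationError("treated_fraction must be in [0, 1]")
        unknown = set(self.perturbed) - set(self.gene_ids)
        if unknown:
            raise ValidationError(f"perturbed references unknown genes: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


@dataclass
class SyntheticDataset:
    """Simulated experiment: both matrix views plus the generating truth.

    ``true_stability_order`` sorts genes by sigma ascending with unperturbed
    genes ranked above perturbed ones.
    """

    quantities: QuantityMatrix
    cq: CqMatrix
    config: SimConfig
    true_stability_order: list[str]
    content_factors: np.ndarray = field(default_factory=lambda: np.empty(0))


def _treated_mask(config: SimConfig) -> np.ndarray:
    n_treated = int(round(config.treated_fraction * config.n_samples))
    mask = np.zeros(config.n_samples, dtype=bool)
    mask[:n_treated] = True
    return mask


def simulate(config: SimConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model; reproducible from seed.

    The sample-content factors and the gene noise are drawn from separate
    child streams of the seed, so changing ``sigma_content`` leaves the
    eps_gs draws bit-identical (used by the cancellation invariance tests).
    The Cq view places values around cycle 25 at efficiency E = 2.
    """
    content_rng, noise_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    genes = config.gene_ids
    c = content_rng.normal(0.0, 1.0, config.n_samples) * config.sigma_content
    eps = noise_rng.normal(0.0, 1.0, (config.n_genes, config.n_samples)) \
        * config.sigma[:, None]
    delta = np.array([config.perturbed.get(g, 0.0) for g in genes])
    treated = _treated_mask(config)
    log2x = (
        np.log2(config.mu)[:, None]
        + c[None, :]
        + delta[:, None] * treated[None, :]
        + eps
    )
    q = QuantityMatrix(genes, config.sample_ids, np.exp2(log2x))
    # Cq = offset_g - log2 x with offset 25 + log2 mu_g -> values near cycle 25
    offsets = 25.0 + np.log2(config.mu)
    cq = CqMatrix(
        genes, config.sample_ids, offsets[:, None] - log2x,
        efficiency=config.efficiency,
    )
    order = sorted(
        range(config.n_genes),
        key=lambda i: (genes[i] in config.perturbed, config.sigma[i], i),
    )
    return SyntheticDataset(
        quantities=q,
        cq=cq,
        config=config,
        true_stability_order=[genes[i] for i in order],
        content_factors=c,
    )


def expected_m(config: SimConfig, gene_j: str) -> float:
    """Closed-form expected M for an unperturbed gene under the model.

    mean over partners k != j of sqrt(sigma_j^2 + sigma_k^2); treatment
    effects are ignored (gene_j must be unperturbed for the form to apply).
    """
    genes = config.gene_ids
    if gene_j not in genes:
        raise ValidationError(f"unknown gene: {gene_j!r}")
    if gene_j in config.perturbed:
        raise ValidationError(f"expected_m is defined for unperturbed genes; {gene_j!r} is perturbed")
    j = genes.index(gene_j)
    others = [i for i in range(config.n_genes) if i != j]
    return float(
        np.mean([math.sqrt(config.sigma[j] ** 2 + config.sigma[i] ** 2) for i in others])
    )


def simulate_experiment_suite(
    base: SimConfig,
    n_experiments: int,
    heterogeneity: float = 0.0,
    seed: int | None = None,
) -> list[SyntheticDataset]:
    """Simulate a family of experiments with jittered per-gene noise levels.

    Each experiment multiplies the base sigma vector by 2**Normal(0,
    heterogeneity) per gene; experiment i uses seed base.seed + i, so a
    single experiment with zero jitter reproduces ``simulate(base)`` exactly.
    """
    if n_experiments < 1:
        raise ValidationError("n_experiments must be >= 1")
    if heterogeneity < 0:
        raise ValidationError("heterogeneity must be >= 0")
    jitter_rng = np.random.default_rng(base.seed if seed is None else seed)
    suite = []
    for i in range(n_experiments):
        factors = np.exp2(jitter_rng.normal(0.0, 1.0, base.n_genes) * heterogeneity)
        cfg = dataclasses.replace(
            base, sigma=np.asarray(base.sigma) * factors, seed=base.seed + i
        )
        suite.append(simulate(cfg))
    return suite


def write_dataset(ds: SyntheticDataset, out_dir: str | Path, delimiter: str = "\t") -> None:
    """Write both matrix views plus a ground-truth sidecar record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(ds.quantities, out / "quantities.tsv", delimiter=delimiter)
    write_matrix(ds.cq, out / "cq.tsv", delimiter=delimiter)
    truth = {
        "seed": ds.config.seed,
        "gene_ids": ds.config.gene_ids,
        "sample_ids": ds.config.sample_ids,
        "mu": [float(v) for v in ds.config.mu],
        "sigma": [float(v) for v in ds.config.sigma],
        "sigma_content": ds.config.sigma_content,
        "perturbed": ds.config.perturbed,
        "treated_fraction": ds.config.treated_fraction,
        "content_factors": [float(v) for v in ds.content_factors],
        "true_stability_order": ds.true_stability_order,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")
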