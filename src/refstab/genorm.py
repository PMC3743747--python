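"""Expression-stability statistics for candidate reference assays.

Implements the geNorm family: pairwise variation V_jk (SD of log2 expression
ratios across samples), the per-gene stability measure M (mean pairwise
variation against all partners), stepwise-exclusion ranking, per-sample
normalization factors (geometric means) and the sequential V_{n,n+1}
criterion for the recommended number of reference genes.

Conventions (fixed for comparability with published M-values): log base 2,
sample standard deviation with the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .qpcr_data import QuantityMatrix

__all__ = [
    "StabilityResult",
    "NfCurve",
    "pairwise_variation",
    "m_value",
    "m_values",
    "rank_stepwise",
    "normalization_factor",
    "v_curve",
    "DEFAULT_V_CUTOFF",
]

DEFAULT_V_CUTOFF = 0.15


@dataclass
class StabilityResult:
    """Stability analysis of one experiment.

    ``m_values`` are computed on the full assay set (the values one would
    print in a per-experiment table); ``ranking`` orders assays least stable
    first, obtained by stepwise exclusion with M recomputed at each step.
    The last two assays cannot be distinguished by the statistic, hence
    ``final_pair_tied`` is always True.
    """

    assay_ids: list[str]
    m_values: dict[str, float]
    ranking: list[str]
    exclusion_trace: list[tuple[str, float]]
    final_pair_tied: bool = True

    def stability_order(self) -> list[str]:
        """Assays from most to least stable (reverse of ``ranking``)."""
        return list(reversed(self.ranking))


@dataclass
class NfCurve:
    """Normalization factors NF_n and sequential pairwise variations.

    ``nf[n]`` is the per-sample geometric mean of the n most stable assays;
    ``v_values[n]`` = SD over samples of log2(NF_n / NF_{n+1}), defined for
    n = 2 .. n_assays-1. ``recommended_n`` is the smallest n with
    V_{n,n+1} < cutoff, or n_assays if the cutoff is never met.
    """

    nf: dict[int, np.ndarray]
    v_values: dict[int, float]
    recommended_n: int
    cutoff: float = DEFAULT_V_CUTOFF


def _log2q(q: QuantityMatrix) -> np.ndarray:
    return np.log2(q.q)


def _tied(a: float, b: float) -> bool:
    """Float-robust equality for M comparisons (distinct code paths may
    produce values differing in the last ulps for mathematically tied M)."""
    return math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12)


def _sd(x: np.ndarray) -> float:
    if x.shape[-1] < 2:
        raise InsufficientDataError("need at least 2 samples")
    return float(np.std(x, ddof=1))


def pairwise_variation(q: QuantityMatrix, assay_j: str, assay_k: str) -> float:
    """SD (n-1 denominator) over samples of log2(q_j / q_k); symmetric."""
    j, k = q.assay_index(assay_j), q.assay_index(assay_k)
    logq = _log2q(q)
    return _sd(logq[j] - logq[k])


def m_value(
    q: QuantityMatrix, assay_j: str, within: Sequence[str] | None = None
) -> float:
    """Stability measure M: mean pairwise variation of assay_j vs partners."""
    within = list(within) if within is not None else list(q.assay_ids)
    if assay_j not in within:
        raise ValidationError(f"assay {assay_j!r} not in the evaluation subset")
    if len(within) < 2:
        raise InsufficientDataError("M requires at least 2 assays")
    return float(
        np.mean([pairwise_variation(q, assay_j, k) for k in within if k != assay_j])
    )


def m_values(
    q: QuantityMatrix, within: Sequence[str] | None = None
) -> dict[str, float]:
    """M for every assay in ``within`` (vectorized over all pairs)."""
    within = list(within) if within is not None else list(q.assay_ids)
    if len(within) < 2:
        raise InsufficientDataError("M requires at least 2 assays")
    idx = [q.assay_index(a) for a in within]
    logq = _log2q(q)[idx]
    n_samples = logq.shape[1]
    if n_samples < 2:
        raise InsufficientDataError("need at least 2 samples")
    # sd[j,k] of log-ratio rows; diagonal zero, excluded from the mean
    diffs = logq[:, None, :] - logq[None, :, :]
    sds = np.std(diffs, axis=2, ddof=1)
    means = (sds.sum(axis=1)) / (len(within) - 1)
    return {a: float(m) for a, m in zip(within, means)}


def rank_stepwise(q: QuantityMatrix) -> StabilityResult:
    """Rank assays by stepwise exclusion of the least stable one.

    At each step M is recomputed within the remaining assay set and the
    argmax-M assay is excluded (appended to the ranking, least stable first).
    Ties take the assay later in input order. The two survivors are appended
    with the lower full-set M last (most stable position); they are mutually
    indistinguishable by the statistic.
    """
    if len(q.assay_ids) < 3:
        raise InsufficientDataError("stepwise ranking requires at least 3 assays")
    full_m = m_values(q)
    current = list(q.assay_ids)
    ranking: list[str] = []
    trace: list[tuple[str, float]] = []
    while len(current) > 2:
        step_m = m_values(q, within=current)
        # ties (within float tolerance) exclude the assay later in input order
        top = max(step_m.values())
        worst = [a for a in current if _tied(step_m[a], top)][-1]
        trace.append((worst, step_m[worst]))
        ranking.append(worst)
        current.remove(worst)
    # survivors: ascending full-set M last, ties alphabetical last
    a, b = current
    if _tied(full_m[a], full_m[b]):
        survivors = sorted(current, reverse=True)
    else:
        survivors = sorted(current, key=lambda g: full_m[g], reverse=True)
    ranking.extend(survivors)
    return StabilityResult(
        assay_ids=list(q.assay_ids),
        m_values=full_m,
        ranking=ranking,
        exclusion_trace=trace,
        final_pair_tied=True,
    )


def normalization_factor(q: QuantityMatrix, assays: Iterable[str]) -> np.ndarray:
    """Per-sample geometric mean of the selected assays' quantities."""
    assays = list(assays)
    if not assays:
        raise ValidationError("normalization_factor requires a non-empty assay subset")
    idx = [q.assay_index(a) for a in assays]
    return np.exp2(np.mean(np.log2(q.q[idx]), axis=0))


def v_curve(
    q: QuantityMatrix,
    ranking: StabilityResult | Sequence[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> NfCurve:
    """Sequential pairwise variation between NF_n and NF_{n+1}.

    Genes are added in stability order (most stable pair first). V_{n,n+1}
    is the sample SD over samples of log2(NF_n / NF_{n+1}).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    order = (
        ranking.stability_order()
        if isinstance(ranking, StabilityResult)
        else list(ranking)
    )
    k = len(order)
    if k < 3:
        raise InsufficientDataError("V-curve requires at least 3 assays")
    nf = {n: normalization_factor(q, order[:n]) for n in range(2, k + 1)}
    v = {n: _sd(np.log2(nf[n] / nf[n + 1])) for n in range(2, k)}
    recommended = next((n for n in range(2, k) if v[n] < cutoff), k)
    return NfCurve(nf=nf, v_values=v, recommended_n=recommended, cutoff=cutoff)
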