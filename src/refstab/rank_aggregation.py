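"""Consensus ordering of weighted ranked lists.

Distance: weighted Spearman footrule. Each list carries per-assay importance
scores (stability M-values); scores are min-max normalized to [0, 1] per
list and attached to *positions*, and the distance between a candidate
ordering and a list is

    sum_t | W(position of t in the list) - W(position of t in the candidate) |.

An unweighted footrule (sum of absolute rank differences) is available as an
alternative. Optimizers: Borda count baseline, exhaustive search (small
instances), and a cross-entropy Monte Carlo scheme over a position
probability matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InstanceSizeError, ValidationError

__all__ = [
    "RankedList",
    "CEParams",
    "AggregationResult",
    "normalize_weights",
    "footrule_distance",
    "total_objective",
    "borda_aggregate",
    "brute_force_aggregate",
    "ce_aggregate",
    "aggregate_table1",
]


@dataclass
class RankedList:
    """One experiment's ordering, best (lowest weight) first.

    ``weights`` are the per-assay importance scores in list order and must be
    non-decreasing (the list is sorted by its own weights).
    """

    experiment_id: str
    assays: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.assays = list(self.assays)
        if len(set(self.assays)) != len(self.assays):
            raise ValidationError(
                f"list {self.experiment_id!r} contains duplicate assays"
            )
        self.weights = np.array(self.weights, dtype=float)
        if self.weights.shape != (len(self.assays),):
            raise ValidationError(
                f"list {self.experiment_id!r}: weights length != assays length"
            )
        if np.any(np.diff(self.weights) < 0):
            raise ValidationError(
                f"list {self.experiment_id!r}: weights must be non-decreasing"
            )


@dataclass
class CEParams:
    """Cross-entropy optimizer hyperparameters.

    ``n_samples_per_iter`` defaults to 10 * k**2 for k items when left None.
    """

    n_samples_per_iter: int | None = None
    elite_fraction: float = 0.1
    smoothing: float = 0.25
    convergence_patience: int = 5
    max_iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_iter is not None and self.n_samples_per_iter < 1:
            raise ValidationError("n_samples_per_iter must be >= 1")
        if not 0 < self.elite_fraction < 1:
            raise ValidationError("elite_fraction must be in (0, 1)")
        if not 0 < self.smoothing <= 1:
            raise ValidationError("smoothing must be in (0, 1]")
        if self.convergence_patience < 1 or self.max_iters < 1:
            raise ValidationError("patience and max_iters must be >= 1")

    def samples_for(self, k: int) -> int:
        return self.n_samples_per_iter if self.n_samples_per_iter else 10 * k * k


@dataclass
class AggregationResult:
    consensus: list[str]
    objective: float
    method: str
    trace: list[float] = field(default_factory=list)
    seed: int | None = None
    per_experiment: dict[str, list[str]] = field(default_factory=dict)


def normalize_weights(l: RankedList) -> RankedList:
    """Min-max normalize weights to [0, 1]; all-equal weights map to zeros.

    Idempotent; returns a new list, inputs untouched.
    """
    w = l.weights
    span = w.max() - w.min()
    if span == 0:
        return replace(l, weights=np.zeros_like(w))
    return replace(l, weights=(w - w.min()) / span)


def _check_same_assays(candidate: Sequence[str], l: RankedList) -> None:
    cand, mine = set(candidate), set(l.assays)
    if cand != mine or len(candidate) != len(l.assays):
        diff = sorted(cand.symmetric_difference(mine))
        raise ValidationError(
            f"assay-set mismatch with list {l.experiment_id!r}: "
            f"symmetric difference {diff}"
        )


def footrule_distance(
    candidate: Sequence[str], l: RankedList, weighted: bool = True
) -> float:
    """Weighted Spearman footrule between a candidate ordering and a list.

    Weights are normalized internally (idempotent), so raw-M lists are
    accepted. With ``weighted=False`` returns the classical footrule
    (sum of absolute rank differences).
    """
    _check_same_assays(candidate, l)
    pos_l = {a: r for r, a in enumerate(l.assays)}
    pos_c = {a: r for r, a in enumerate(candidate)}
    if not weighted:
        return float(sum(abs(pos_l[a] - pos_c[a]) for a in l.assays))
    w = normalize_weights(l).weights
    return float(sum(abs(w[pos_l[a]] - w[pos_c[a]]) for a in l.assays))


def total_objective(
    candidate: Sequence[str], lists: Sequence[RankedList], weighted: bool = True
) -> float:
    """Sum of footrule distances from the candidate to every input list."""
    if not lists:
        raise ValidationError("need at least one ranked list")
    return float(sum(footrule_distance(candidate, l, weighted=weighted) for l in lists))


def _common_items(lists: Sequence[RankedList]) -> list[str]:
    items = sorted(lists[0].assays)
    for l in lists[1:]:
        _check_same_assays(items, l)
    return items


def borda_aggregate(lists: Sequence[RankedList]) -> AggregationResult:
    """Order assays by ascending mean rank across lists; ties alphabetical."""
    if not lists:
        raise ValidationError("need at least one ranked list")
    items = _common_items(lists)
    mean_rank = {
        a: float(np.mean([l.assays.index(a) + 1 for l in lists])) for a in items
    }
    consensus = sorted(items, key=lambda a: (mean_rank[a], a))
    return AggregationResult(
        consensus=consensus,
        objective=total_objective(consensus, lists),
        method="borda",
    )


def brute_force_aggregate(lists: Sequence[RankedList]) -> AggregationResult:
    """Exhaustive minimizer of the total objective; ties lexicographic.

    Only for instances of at most 8 assays (8! = 40320 permutations).
    """
    if not lists:
        raise ValidationError("need at least one ranked list")
    items = _common_items(lists)
    if len(items) > 8:
        raise InstanceSizeError(
            f"brute force limited to 8 assays, got {len(items)}"
        )
    norm = [normalize_weights(l) for l in lists]
    best: tuple[float, tuple[str, ...]] | None = None
    for perm in itertools.permutations(items):  # lexicographic order
        obj = total_objective(perm, norm)
        if best is None or obj < best[0] - 1e-12:
            best = (obj, perm)
    assert best is not None
    return AggregationResult(
        consensus=list(best[1]), objective=best[0], method="brute"
    )


def _sample_permutations(
    P: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n permutations: per position, draw among unused items from P[:, pos]."""
    k = P.shape[0]
    avail = np.ones((n, k), dtype=bool)
    out = np.empty((n, k), dtype=np.int64)
    rows = np.arange(n)
    for j in range(k):
        w = np.where(avail, P[:, j][None, :], 0.0)
        totals = w.sum(axis=1)
        dead = totals <= 0  # column mass exhausted -> uniform over remaining
        if dead.any():
            w[dead] = avail[dead].astype(float)
            totals = w.sum(axis=1)
        cdf = np.cumsum(w, axis=1)
        u = rng.random(n) * totals
        choice = (cdf < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, k - 1)
        # float-boundary guard: ensure the chosen item is actually available
        bad = ~avail[rows, choice]
        if bad.any():
            for r in np.flatnonzero(bad):
                choice[r] = np.flatnonzero(avail[r])[0]
        out[:, j] = choice
        avail[rows, choice] = False
    return out


def _batch_objectives(
    positions: np.ndarray,
    weights: list[np.ndarray],
    list_pos: list[np.ndarray],
) -> np.ndarray:
    """Vectorized total objective; positions[s, item] = item's rank in sample s."""
    total = np.zeros(positions.shape[0])
    for w, lp in zip(weights, list_pos):
        total += np.abs(w[lp][None, :] - w[positions]).sum(axis=1)
    return total


def ce_aggregate(
    lists: Sequence[RankedList], params: CEParams | None = None
) -> AggregationResult:
    """Cross-entropy Monte Carlo minimization of the total footrule objective.

    Maintains a k x k item-by-position probability matrix initialized
    uniform; each iteration samples permutations, keeps the elite fraction,
    re-estimates the matrix from elite frequencies and smooths it into the
    previous one. Tracks the best candidate ever sampled and stops after
    ``convergence_patience`` iterations without improvement. The returned
    consensus is never worse than the Borda baseline (argmin of the two).
    Fully reproducible from ``params.seed``.
    """
    if not lists:
        raise ValidationError("need at least one ranked list")
    params = params or CEParams()
    items = _common_items(lists)
    k = len(items)
    item_index = {a: i for i, a in enumerate(items)}
    norm = [normalize_weights(l) for l in lists]
    weights = [l.weights for l in norm]
    # list_pos[i] = position of canonical item i in list l
    list_pos = [
        np.array([l.assays.index(a) for a in items], dtype=np.int64) for l in norm
    ]

    n = params.samples_for(k)
    n_elite = max(1, math.ceil(params.elite_fraction * n))
    rng = np.random.default_rng(params.seed)
    P = np.full((k, k), 1.0 / k)

    best_obj = math.inf
    best_perm: np.ndarray | None = None
    trace: list[float] = []
    stall = 0
    for _ in range(params.max_iters):
        perms = _sample_permutations(P, n, rng)
        positions = np.argsort(perms, axis=1)
        objs = _batch_objectives(positions, weights, list_pos)
        order = np.argsort(objs, kind="stable")
        elite = perms[order[:n_elite]]
        if objs[order[0]] < best_obj - 1e-12:
            best_obj = float(objs[order[0]])
            best_perm = perms[order[0]].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_obj)
        if stall >= params.convergence_patience:
            break
        P_new = np.zeros((k, k))
        for j in range(k):
            P_new[:, j] = np.bincount(elite[:, j], minlength=k)
        P_new /= n_elite
        P = params.smoothing * P_new + (1.0 - params.smoothing) * P

    assert best_perm is not None
    consensus = [items[i] for i in best_perm]
    objective = best_obj
    borda = borda_aggregate(lists)
    if borda.objective < objective - 1e-12:  # guaranteed >= baseline
        consensus, objective = borda.consensus, borda.objective
    return AggregationResult(
        consensus=consensus,
        objective=float(objective),
        method="ce",
        trace=trace,
        seed=params.seed,
    )


def aggregate_table1(
    t, method: str = "ce", params: CEParams | None = None
) -> AggregationResult:
    """Aggregate an M-value table's per-experiment rankings into a consensus.

    Builds one ranked list per experiment (M ascending, printed-column-order
    ties), normalizes weights per list, and dispatches to the requested
    optimizer. Per-experiment orderings are recorded on the result.
    """
    from .qpcr_data import table_to_ranked_lists  # local import: avoids cycle

    lists = [normalize_weights(l) for l in table_to_ranked_lists(t)]
    if method == "ce":
        result = ce_aggregate(lists, params)
    elif method == "borda":
        result = borda_aggregate(lists)
    elif method == "brute":
        result = brute_force_aggregate(lists)
    else:
        raise ValidationError(f"unknown aggregation method: {method!r}")
    result.per_experiment = {l.experiment_id: list(l.assays) for l in lists}
    return result
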