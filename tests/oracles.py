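"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and stdlib-only (math/statistics/itertools): explicit
double loops over dict-of-lists data, no numpy, no shared code with the
package under test.
"""

from __future__ import annotations

import itertools
import math
import statistics


def naive_pairwise_variation(q: dict[str, list[float]], j: str, k: str) -> float:
    ratios = [math.log2(a / b) for a, b in zip(q[j], q[k])]
    return statistics.stdev(ratios)


def naive_m_value(q: dict[str, list[float]], j: str, within: list[str]) -> float:
    others = [k for k in within if k != j]
    return sum(naive_pairwise_variation(q, j, k) for k in others) / len(others)


def naive_rank_stepwise(q: dict[str, list[float]], assay_order: list[str]):
    """Returns (ranking least-stable-first, full-set M dict, trace)."""
    full_m = {a: naive_m_value(q, a, assay_order) for a in assay_order}
    current = list(assay_order)
    ranking: list[str] = []
    trace: list[tuple[str, float]] = []
    while len(current) > 2:
        step_m = {a: naive_m_value(q, a, current) for a in current}
        # ties (within float tolerance): assay later in input order is excluded
        best_val = max(step_m.values())
        worst = [
            a for a in current
            if math.isclose(step_m[a], best_val, rel_tol=1e-9, abs_tol=1e-12)
        ][-1]
        trace.append((worst, step_m[worst]))
        ranking.append(worst)
        current.remove(worst)
    a, b = current
    if math.isclose(full_m[a], full_m[b], rel_tol=1e-9, abs_tol=1e-12):
        survivors = sorted(current, reverse=True)
    else:
        survivors = sorted(current, key=lambda g: full_m[g], reverse=True)
    return ranking + survivors, full_m, trace


def naive_geometric_mean(values: list[float]) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def naive_v_curve(q: dict[str, list[float]], stability_order: list[str]):
    """V_{n,n+1} by explicit geometric means; returns dict n -> V."""
    n_samples = len(next(iter(q.values())))
    k = len(stability_order)
    nf = {}
    for n in range(2, k + 1):
        subset = stability_order[:n]
        nf[n] = [
            naive_geometric_mean([q[g][s] for g in subset]) for s in range(n_samples)
        ]
    v = {}
    for n in range(2, k):
        ratios = [math.log2(nf[n][s] / nf[n + 1][s]) for s in range(n_samples)]
        v[n] = statistics.stdev(ratios)
    return v


def naive_normalize(weights: list[float]) -> list[float]:
    lo, hi = min(weights), max(weights)
    if hi == lo:
        return [0.0] * len(weights)
    return [(w - lo) / (hi - lo) for w in weights]


def naive_footrule(candidate: list[str], assays: list[str], weights: list[float]) -> float:
    w = naive_normalize(weights)
    pos_l = {a: i for i, a in enumerate(assays)}
    pos_c = {a: i for i, a in enumerate(candidate)}
    return sum(abs(w[pos_l[a]] - w[pos_c[a]]) for a in assays)


def naive_total(candidate: list[str], lists: list[tuple[list[str], list[float]]]) -> float:
    return sum(naive_footrule(candidate, assays, weights) for assays, weights in lists)


def naive_brute_force(lists: list[tuple[list[str], list[float]]]):
    """Exhaustive minimum of the total footrule; first lexicographic winner."""
    items = sorted(lists[0][0])
    best_obj, best_perm = math.inf, None
    for perm in itertools.permutations(items):
        obj = naive_total(list(perm), lists)
        if obj < best_obj - 1e-12:
            best_obj, best_perm = obj, list(perm)
    return best_perm, best_obj


def naive_borda(lists: list[tuple[list[str], list[float]]]) -> list[str]:
    items = sorted(lists[0][0])
    mean_rank = {
        a: sum(assays.index(a) + 1 for assays, _ in lists) / len(lists) for a in items
    }
    return sorted(items, key=lambda a: (mean_rank[a], a))
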