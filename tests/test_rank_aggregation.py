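import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.errors import InstanceSizeError, ValidationError
from refstab.qpcr_data import load_table1_fixture, table_to_ranked_lists
from refstab.rank_aggregation import (
    AggregationResult,
    CEParams,
    RankedList,
    aggregate_table1,
    borda_aggregate,
    brute_force_aggregate,
    ce_aggregate,
    footrule_distance,
    normalize_weights,
    total_objective,
)

from . import oracles


def make_list(exp: str, assays: list[str], weights=None) -> RankedList:
    if weights is None:
        weights = list(range(len(assays)))
    return RankedList(exp, assays, np.asarray(weights, float))


def random_instance(seed: int, k: int = 5, n_lists: int = 4):
    """Random weighted lists over k assays (weights sorted ascending)."""
    rng = np.random.default_rng(seed)
    items = [f"A{i}" for i in range(k)]
    lists = []
    for e in range(n_lists):
        order = list(rng.permutation(items))
        weights = np.sort(rng.uniform(0.05, 1.5, k))
        lists.append(RankedList(f"E{e}", order, weights))
    return lists


class TestRankedList:
    def test_duplicate_assays_rejected(self):
        with pytest.raises(ValidationError):
            make_list("e", ["a", "a", "b"])

    def test_decreasing_weights_rejected(self):
        with pytest.raises(ValidationError):
            RankedList("e", ["a", "b"], np.array([1.0, 0.5]))


class TestNormalizeWeights:
    def test_endpoints(self):
        l = make_list("e", list("abcd"), [0.06, 0.10, 0.20, 0.29])
        n = normalize_weights(l)
        assert n.weights[0] == 0.0
        assert n.weights[-1] == 1.0

    def test_degenerate_all_equal(self):
        l = make_list("e", list("abc"), [0.3, 0.3, 0.3])
        np.testing.assert_array_equal(normalize_weights(l).weights, [0, 0, 0])

    def test_idempotent(self):
        l = make_list("e", list("abc"), [0.1, 0.5, 0.8])
        once = normalize_weights(l)
        twice = normalize_weights(once)
        np.testing.assert_allclose(once.weights, twice.weights)

    def test_input_unmodified(self):
        w = np.array([0.1, 0.5, 0.8])
        l = RankedList("e", list("abc"), w.copy())
        normalize_weights(l)
        np.testing.assert_array_equal(l.weights, w)


class TestFootrule:
    def test_identity_is_zero(self):
        l = make_list("e", list("abc"), [0.0, 0.5, 1.0])
        assert footrule_distance(list("abc"), l) == 0.0

    def test_reversal_hand_computed(self):
        l = make_list("e", list("abc"), [0.0, 0.5, 1.0])
        assert footrule_distance(list("cba"), l) == pytest.approx(2.0)

    def test_all_zero_weights_degenerate(self):
        l = make_list("e", list("abc"), [0.3, 0.3, 0.3])
        for perm in itertools.permutations("abc"):
            assert footrule_distance(list(perm), l) == 0.0

    def test_assay_mismatch_names_symmetric_difference(self):
        l = make_list("e", ["a", "b", "c"])
        with pytest.raises(ValidationError, match=r"\['c', 'd'\]"):
            footrule_distance(["a", "b", "d"], l)

    def test_unweighted_variant(self):
        l = make_list("e", list("abc"))
        assert footrule_distance(list("cba"), l, weighted=False) == 4.0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            (l,) = random_instance(int(rng.integers(1e6)), k=6, n_lists=1)
            cand = list(np.random.default_rng(int(rng.integers(1e6))).permutation(l.assays))
            assert footrule_distance(cand, l) == pytest.approx(
                oracles.naive_footrule(cand, l.assays, list(l.weights)), rel=1e-12
            )

    def test_relabeling_invariance(self):
        l = make_list("e", list("abc"), [0.1, 0.4, 0.9])
        relabel = {"a": "x", "b": "y", "c": "z"}
        l2 = make_list("e", [relabel[a] for a in l.assays], list(l.weights))
        for perm in itertools.permutations("abc"):
            d1 = footrule_distance(list(perm), l)
            d2 = footrule_distance([relabel[a] for a in perm], l2)
            assert d1 == pytest.approx(d2)


class TestTotalObjective:
    def test_single_list_self_zero(self):
        l = make_list("e", list("abcd"))
        assert total_objective(l.assays, [l]) == 0.0

    def test_additivity_under_duplication(self):
        lists = random_instance(3)
        cand = sorted(lists[0].assays)
        assert total_objective(cand, lists + lists) == pytest.approx(
            2 * total_objective(cand, lists)
        )

    def test_lower_bounded_by_brute_optimum(self):
        lists = random_instance(11, k=4)
        best = brute_force_aggregate(lists)
        rng = np.random.default_rng(0)
        for _ in range(10):
            cand = list(rng.permutation(sorted(lists[0].assays)))
            assert total_objective(cand, lists) >= best.objective - 1e-12


class TestBorda:
    def test_hand_enumerated_example(self):
        lists = [
            make_list("1", ["A", "B", "C"]),
            make_list("2", ["A", "C", "B"]),
            make_list("3", ["B", "A", "C"]),
        ]
        res = borda_aggregate(lists)
        # mean ranks: A = 4/3, B = 2, C = 8/3
        assert res.consensus == ["A", "B", "C"]
        assert res.method == "borda"

    def test_identical_lists(self):
        lists = [make_list(str(i), ["c", "a", "b"]) for i in range(4)]
        assert borda_aggregate(lists).consensus == ["c", "a", "b"]

    def test_single_list(self):
        l = make_list("e", ["b", "c", "a"])
        assert borda_aggregate([l]).consensus == ["b", "c", "a"]

    def test_tie_broken_by_assay_id(self):
        lists = [make_list("1", ["x", "y"]), make_list("2", ["y", "x"])]
        assert borda_aggregate(lists).consensus == ["x", "y"]

    def test_matches_naive_oracle(self):
        for seed in range(10):
            lists = random_instance(seed)
            expected = oracles.naive_borda([(l.assays, list(l.weights)) for l in lists])
            assert borda_aggregate(lists).consensus == expected


class TestBruteForce:
    def test_single_list_identity(self):
        l = make_list("e", ["b", "a", "c"], [0.1, 0.5, 0.9])
        res = brute_force_aggregate([l])
        assert res.consensus == ["b", "a", "c"]
        assert res.objective == 0.0

    def test_two_reversed_lists(self):
        w = [0.0, 0.5, 1.0]
        lists = [make_list("1", list("abc"), w), make_list("2", list("cba"), w)]
        res = brute_force_aggregate(lists)
        # naive enumeration over all 6 permutations gives the same minimum
        perm, obj = oracles.naive_brute_force([(l.assays, list(l.weights)) for l in lists])
        assert res.objective == pytest.approx(obj)
        assert res.consensus == perm

    def test_never_worse_than_borda(self):
        for seed in range(20):
            lists = random_instance(seed)
            assert (
                brute_force_aggregate(lists).objective
                <= borda_aggregate(lists).objective + 1e-12
            )

    def test_size_limit(self):
        l = make_list("e", [f"a{i}" for i in range(9)])
        with pytest.raises(InstanceSizeError):
            brute_force_aggregate([l])

    def test_matches_naive_oracle(self):
        for seed in range(10):
            lists = random_instance(seed, k=4, n_lists=3)
            perm, obj = oracles.naive_brute_force(
                [(l.assays, list(l.weights)) for l in lists]
            )
            res = brute_force_aggregate(lists)
            assert res.objective == pytest.approx(obj, rel=1e-12)
            assert res.consensus == perm


class TestCE:
    def test_identical_lists_recovered(self):
        lists = [make_list(str(i), ["d", "b", "a", "c"], [0.1, 0.2, 0.4, 0.9])
                 for i in range(5)]
        res = ce_aggregate(lists, CEParams(seed=3))
        assert res.consensus == ["d", "b", "a", "c"]
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        lists = random_instance(42)
        a = ce_aggregate(lists, CEParams(seed=9))
        b = ce_aggregate(lists, CEParams(seed=9))
        assert a.consensus == b.consensus
        assert a.trace == b.trace
        assert a.objective == b.objective

    def test_seed_recorded(self):
        lists = random_instance(1)
        assert ce_aggregate(lists, CEParams(seed=77)).seed == 77

    def test_attains_brute_optimum_mostly(self):
        hits = 0
        for seed in range(30):
            lists = random_instance(seed)
            opt = brute_force_aggregate(lists).objective
            ce = ce_aggregate(lists, CEParams(seed=seed)).objective
            assert ce >= opt - 1e-12  # never beats the global optimum
            hits += ce <= opt + 1e-12
        assert hits >= 29

    def test_never_worse_than_borda(self):
        for seed in range(15):
            lists = random_instance(seed, k=6, n_lists=5)
            ce = ce_aggregate(lists, CEParams(seed=seed))
            assert ce.objective <= borda_aggregate(lists).objective + 1e-12

    def test_consensus_is_permutation(self):
        lists = random_instance(5, k=7, n_lists=3)
        res = ce_aggregate(lists, CEParams(seed=0))
        assert sorted(res.consensus) == sorted(lists[0].assays)

    def test_trace_is_monotone_best_ever(self):
        lists = random_instance(8)
        res = ce_aggregate(lists, CEParams(seed=2))
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            CEParams(elite_fraction=0.0)
        with pytest.raises(ValidationError):
            CEParams(smoothing=1.5)
        with pytest.raises(ValidationError):
            CEParams(n_samples_per_iter=0)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_property_ce_bounded_by_borda_and_brute(self, seed):
        lists = random_instance(seed, k=4, n_lists=3)
        opt = brute_force_aggregate(lists).objective
        borda = borda_aggregate(lists).objective
        ce = ce_aggregate(lists, CEParams(seed=seed)).objective
        assert opt - 1e-12 <= ce <= borda + 1e-12


class TestAggregateTable1:
    def test_ce_puts_alu_first(self):
        t = load_table1_fixture()
        res = aggregate_table1(t, method="ce", params=CEParams(seed=0))
        assert res.consensus[0] == "Alu-Sq"
        assert res.method == "ce"
        assert len(res.per_experiment) == 19

    def test_borda_permutation_contract(self):
        t = load_table1_fixture()
        res = aggregate_table1(t, method="borda")
        assert sorted(res.consensus) == sorted(t.assay_ids)

    def test_ce_agrees_with_brute_on_subset(self):
        """6-assay column subset: CE finds the exhaustive optimum."""
        from refstab.qpcr_data import MValueTable

        t = load_table1_fixture()
        keep = ["Alu-Sq", "TBP", "GAPDH", "B2M", "ACTB", "RPL13A"]
        idx = [t.assay_ids.index(a) for a in keep]
        sub = MValueTable(t.experiment_ids, keep, t.m[:, idx])
        ce = aggregate_table1(sub, method="ce", params=CEParams(seed=4))
        brute = aggregate_table1(sub, method="brute")
        assert ce.objective == pytest.approx(brute.objective, abs=1e-9)

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            aggregate_table1(load_table1_fixture(), method="simulated-annealing")
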