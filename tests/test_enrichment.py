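"""Enrichment core: ranking, running sum, ES, permutation p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netenrich import (
    AssociationMap,
    ModelSpec,
    NetworkPartition,
    SubjectDataset,
    ecdf_extremeness_diagnostic,
    enrichment_score,
    exhaustive_nest_pvalue,
    nest_test,
    permutation_pvalue,
    rank_vertices,
    running_sum,
)
from netenrich.enrichment import _es_many, _es_one

from conftest import make_pheno


def amap_of(T, ids=None):
    ids = ids or [f"v{i}" for i in range(len(T))]
    return AssociationMap(np.asarray(T, float), ids, "age", "pearson")


def part_of(member, ids=None):
    member = np.asarray(member, bool)
    ids = ids or [f"v{i}" for i in range(len(member))]
    return NetworkPartition(member.astype(int), ids, target_label=1)


class TestRanking:
    def test_descending_order(self):
        ranked = rank_vertices(amap_of([-1.0, 3.0, 2.0]), part_of([1, 0, 0]))
        assert list(ranked.order) == [1, 2, 0]
        assert list(ranked.sorted_T) == [3.0, 2.0, -1.0]

    def test_ties_break_by_ascending_index(self):
        ranked = rank_vertices(amap_of([1.0, 1.0, 1.0]), part_of([0, 1, 0]))
        assert list(ranked.order) == [0, 1, 2]

    def test_matches_library_sort(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=50)
        ranked = rank_vertices(amap_of(T), part_of(rng.integers(0, 2, 50)))
        assert np.allclose(ranked.sorted_T, np.sort(T)[::-1])

    def test_misaligned_ids_raise_with_offender(self):
        with pytest.raises(ValueError, match="v0.*x0|misaligned"):
            rank_vertices(
                amap_of([1.0, 2.0], ["v0", "v1"]),
                NetworkPartition([1, 0], ["x0", "v1"], 1),
            )


class TestRunningSum:
    def test_worked_example(self):
        # V=5, sorted T = (3,2,1,-1,-2), network = the two top-ranked
        # locations: hand computation gives RS = (0, 0.6, 1, 2/3, 1/3, 0)
        amap = amap_of([3.0, 2.0, 1.0, -1.0, -2.0])
        part = part_of([1, 1, 0, 0, 0])
        rs = running_sum(rank_vertices(amap, part))
        assert np.allclose(rs.RS, [0.0, 0.6, 1.0, 2 / 3, 1 / 3, 0.0])
        assert enrichment_score(rs) == pytest.approx(1.0)

    def test_bottom_ranked_singleton_descends_then_returns(self):
        amap = amap_of([3.0, 2.0, 1.0, -2.0])
        part = part_of([0, 0, 0, 1])
        rs = running_sum(rank_vertices(amap, part))
        assert np.all(np.diff(rs.RS[:-1]) < 0)
        assert rs.RS[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("variant", ["weighted_one_sided", "unweighted_two_sided"])
    def test_conservation_and_bounds_random_inputs(self, variant):
        rng = np.random.default_rng(1)
        for _ in range(200):
            V = rng.integers(3, 40)
            T = rng.normal(size=V)
            member = np.zeros(V, bool)
            member[rng.choice(V, rng.integers(1, V), replace=False)] = True
            rs = running_sum(
                rank_vertices(amap_of(T), part_of(member)), variant
            )
            assert abs(rs.RS[-1]) < 1e-12
            assert np.all(rs.RS <= 1 + 1e-12) and np.all(rs.RS >= -1 - 1e-12)
            es = enrichment_score(rs)
            assert 0.0 <= es <= 1.0 + 1e-12

    def test_all_zero_in_network_statistics_rejected(self):
        amap = amap_of([0.0, 0.0, 1.0])
        part = part_of([1, 1, 0])
        with pytest.raises(ValueError, match="zero"):
            running_sum(rank_vertices(amap, part))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=30), st.data())
    def test_sign_and_scale_invariance(self, vals, data):
        T = np.asarray(vals) + np.random.default_rng(0).normal(0, 1e-6, len(vals))
        member = np.zeros(len(T), bool)
        k = data.draw(st.integers(1, len(T) - 1))
        member[:k] = True
        if np.abs(T[member]).sum() == 0 or np.abs(T[~member]).sum() == 0:
            return
        es = _es_one(T, member, "weighted_one_sided")
        assert _es_one(-T, member, "weighted_one_sided") == pytest.approx(es)
        assert _es_one(3.7 * T, member, "weighted_one_sided") == pytest.approx(es)

    def test_vectorized_es_matches_columnwise_loop(self):
        rng = np.random.default_rng(2)
        Tmat = rng.normal(size=(30, 25))
        member = np.zeros(30, bool)
        member[rng.choice(30, 8, replace=False)] = True
        got = _es_many(Tmat, member, "weighted_one_sided")
        want = [_es_one(Tmat[:, k], member, "weighted_one_sided") for k in range(25)]
        assert np.allclose(got, want)


class TestPermutationPvalue:
    def test_direct_count(self):
        assert permutation_pvalue(0.5, np.array([0.2, 0.4, 0.6])) == pytest.approx(0.5)

    def test_all_ties_with_strict_inequality(self):
        null = np.full(99, 0.3)
        assert permutation_pvalue(0.3, null) == pytest.approx(1 / 100)
        assert permutation_pvalue(0.3, null, tie_ge=True) == pytest.approx(1.0)

    def test_boundaries(self):
        null = np.linspace(0.1, 0.9, 999)
        assert permutation_pvalue(1.0, null) == pytest.approx(1 / 1000)
        assert permutation_pvalue(0.0, null) == pytest.approx(1.0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(0.5, np.array([]))


class TestNestTest:
    @pytest.fixture
    def small_data(self):
        rng = np.random.default_rng(4)
        pheno = make_pheno(20, seed=4)
        X = rng.normal(size=(20, 15))
        return SubjectDataset(
            X=X, location_ids=[f"v{i}" for i in range(15)], phenotypes=pheno
        )

    def test_reproducible_and_bounded(self, small_data):
        part = part_of([1] * 5 + [0] * 10)
        spec = ModelSpec(effect="age", stat_kind="pearson")
        a = nest_test(small_data, part, spec, K=99, seed=5)
        b = nest_test(small_data, part, spec, K=99, seed=5)
        assert a.p_value == b.p_value
        assert np.allclose(a.null_es, b.null_es)
        assert 1 / 100 <= a.p_value <= 1.0
        assert 0.0 <= a.es_obs <= 1.0

    def test_strong_signal_attains_minimum_pvalue(self):
        rng = np.random.default_rng(6)
        pheno = make_pheno(40, seed=6)
        g = pheno["age"].to_numpy() - pheno["age"].mean()
        X = np.column_stack(
            [10 * g + rng.normal(0, 0.1, 40) for _ in range(5)]
            + [rng.normal(0, 1, 40) for _ in range(15)]
        )
        data = SubjectDataset(
            X=X, location_ids=[f"v{i}" for i in range(20)], phenotypes=pheno
        )
        res = nest_test(
            data, part_of([1] * 5 + [0] * 15), ModelSpec(effect="age", stat_kind="pearson"),
            K=99, seed=1,
        )
        assert res.p_value == pytest.approx(1 / 100)

    def test_invalid_permutation_count(self, small_data):
        with pytest.raises(ValueError, match="K"):
            nest_test(
                small_data, part_of([1] * 5 + [0] * 10),
                ModelSpec(effect="age", stat_kind="pearson"), K=0, seed=1,
            )

    def test_shared_null_maps_across_networks(self, small_data):
        spec = ModelSpec(effect="age", stat_kind="pearson")
        parts = [part_of([1] * 5 + [0] * 10), part_of([0] * 10 + [1] * 5)]
        multi = nest_test(small_data, parts, spec, K=49, seed=9)
        singles = [nest_test(small_data, p, spec, K=49, seed=9) for p in parts]
        for m, s in zip(multi, singles):
            assert m.p_value == s.p_value

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        # oracle: all 720 orderings of the phenotype across 6 subjects
        rng = np.random.default_rng(12)
        pheno = make_pheno(6, seed=12)
        X = rng.normal(size=(6, 20))
        X[:, :6] += 0.3 * (pheno["age"].to_numpy() - pheno["age"].mean())[:, None]
        data = SubjectDataset(
            X=X, location_ids=[f"v{i}" for i in range(20)], phenotypes=pheno
        )
        part = part_of([1] * 6 + [0] * 14)
        spec = ModelSpec(effect="age", stat_kind="pearson")
        p_exact = exhaustive_nest_pvalue(data, part, spec)
        p_mc = nest_test(data, part, spec, K=719, seed=99).p_value
        se = np.sqrt(p_exact * (1 - p_exact) / 719)
        assert abs(p_mc - p_exact) <= 2 * se

    def test_freedman_lane_scheme_runs_and_is_reproducible(self, small_data):
        part = part_of([1] * 5 + [0] * 10)
        spec = ModelSpec(effect="age", stat_kind="ols_wald")
        a = nest_test(small_data, part, spec, K=49, seed=2, scheme="freedman_lane")
        b = nest_test(small_data, part, spec, K=49, seed=2, scheme="freedman_lane")
        assert a.p_value == b.p_value
        assert 1 / 50 <= a.p_value <= 1.0


class TestPartitionAndDiagnostic:
    def test_partition_rejects_empty_or_full_network(self):
        with pytest.raises(ValueError, match="not present"):
            NetworkPartition([2, 2, 2], ["a", "b", "c"], target_label=1)
        with pytest.raises(ValueError, match="every location"):
            NetworkPartition([1, 1, 1], ["a", "b", "c"], target_label=1)

    def test_identical_distributions_coincide(self):
        T = np.array([1.0, -2.0, 3.0, 1.0, -2.0, 3.0])
        curves = ecdf_extremeness_diagnostic(amap_of(T), part_of([1, 1, 1, 0, 0, 0]))
        assert np.allclose(curves["in_gt"], curves["out_gt"])
        assert np.allclose(curves["in_lt"], curves["out_lt"])

    def test_scaled_network_dominates_upper_tail(self):
        T_out = np.array([0.5, 1.0, -0.5, -1.0])
        T = np.concatenate([2 * T_out, T_out])
        curves = ecdf_extremeness_diagnostic(
            amap_of(T), part_of([1, 1, 1, 1, 0, 0, 0, 0])
        )
        assert np.all(curves["in_gt"] >= curves["out_gt"])

    def test_curves_match_direct_counting(self):
        rng = np.random.default_rng(8)
        T = rng.normal(size=40)
        member = np.zeros(40, bool)
        member[:15] = True
        curves = ecdf_extremeness_diagnostic(amap_of(T), part_of(member))
        for w, got in zip(curves["w_positive"], curves["in_gt"]):
            assert got == pytest.approx(np.mean(T[member] > w))
        for w, got in zip(curves["w_negative"], curves["out_lt"]):
            assert got == pytest.approx(np.mean(T[~member] < w))
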