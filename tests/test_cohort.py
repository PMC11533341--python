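"""Presence matrix, differential filter, Venn, saturation, subsampling, rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hervwha import (
    AlignedRead,
    PresenceMatrix,
    build_presence_matrix,
    depth_rank_test,
    flag_significant_loci,
    saturation_curve,
    shared_unique,
    subsample_reads,
    unique_case_loci,
)
from hervwha.scoring import LocusScore, SampleCalls

from oracles import exact_mannwhitney


def _sample(sid, calls, condition=""):
    """SampleCalls from {locus: call}; depth 10 for positives, 1 otherwise."""
    scores = {
        lid: LocusScore(lid, 10.0 if c == "positive" else 1.0, 10, 10, 10, c)
        for lid, c in calls.items()
    }
    return SampleCalls(sample_id=sid, condition_label=condition, scores=scores)


def _random_matrix(rng, n_loci=20, n_samples=8):
    loci = [f"L{i}" for i in range(n_loci)]
    sids = [f"s{i}" for i in range(n_samples)]
    calls = pd.DataFrame(
        rng.choice(["positive", "negative", "uncallable"], size=(n_loci, n_samples), p=[0.3, 0.6, 0.1]),
        index=pd.Index(loci, name="locus_id"), columns=sids,
    )
    depths = pd.DataFrame(
        rng.uniform(0, 20, size=(n_loci, n_samples)),
        index=calls.index, columns=sids,
    )
    return PresenceMatrix(calls=calls, depths=depths, conditions={s: "" for s in sids})


class TestPresenceMatrix:
    def test_cells_equal_sample_calls(self):
        a = _sample("a", {"L1": "positive", "L2": "negative", "L3": "uncallable"})
        b = _sample("b", {"L1": "negative", "L2": "negative", "L3": "positive"})
        m = build_presence_matrix([a, b])
        assert m.calls.shape == (3, 2)
        assert m.calls.loc["L1", "a"] == "positive"
        assert m.depths.loc["L3", "b"] == 10.0

    def test_mismatched_catalogs_rejected(self):
        a = _sample("a", {"L1": "positive"})
        b = _sample("b", {"L2": "positive"})
        with pytest.raises(ValueError, match="different catalog"):
            build_presence_matrix([a, b])

    def test_tsv_round_trip_preserves_every_cell(self, tmp_path, small_cohort_matrix):
        calls_p, depths_p = tmp_path / "calls.tsv", tmp_path / "depths.tsv"
        small_cohort_matrix.to_tsv(calls_p, depths_p)
        back = PresenceMatrix.from_tsv(calls_p, depths_p)
        assert back.calls.equals(small_cohort_matrix.calls)
        assert (back.depths.values == small_cohort_matrix.depths.values).all()
        assert back.conditions == small_cohort_matrix.conditions


class TestUniqueCaseLoci:
    def _matrix(self):
        samples = [
            _sample("c1", {"L1": "negative", "L2": "positive", "L3": "negative"}),
            _sample("c2", {"L1": "negative", "L2": "negative", "L3": "uncallable"}),
            _sample("c3", {"L1": "negative", "L2": "negative", "L3": "negative"}),
            _sample("k1", {"L1": "positive", "L2": "positive", "L3": "negative"}),
            _sample("k2", {"L1": "negative", "L2": "positive", "L3": "negative"}),
        ]
        return build_presence_matrix(samples)

    def test_negative_in_all_controls_one_case_positive_included(self):
        m = self._matrix()
        assert "L1" in unique_case_loci(m, {"c1", "c2", "c3"}, {"k1", "k2"})

    def test_any_control_positive_excludes(self):
        m = self._matrix()
        assert "L2" not in unique_case_loci(m, {"c1", "c2", "c3"}, {"k1", "k2"})

    def test_no_case_positive_gives_empty(self):
        m = self._matrix()
        assert unique_case_loci(m, {"c1", "c2", "c3"}, set()) == set()

    def test_uncallable_control_counts_as_non_positive_by_default(self):
        m = self._matrix()
        samples = [
            _sample("c1", {"L4": "uncallable"}),
        ]
        m2 = build_presence_matrix(
            [_sample("c1", {"L4": "uncallable"}), _sample("k1", {"L4": "positive"})]
        )
        assert unique_case_loci(m2, {"c1"}, {"k1"}) == {"L4"}
        assert unique_case_loci(m2, {"c1"}, {"k1"}, strict_negative=True) == set()

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError, match="control"):
            unique_case_loci(self._matrix(), set(), {"k1"})

    def test_growing_control_pool_only_shrinks_unique_set(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            m = _random_matrix(rng)
            cases = ["s6", "s7"]
            small = unique_case_loci(m, ["s0", "s1"], cases)
            large = unique_case_loci(m, ["s0", "s1", "s2", "s3"], cases)
            assert large <= small


class TestVenn:
    def test_exact_partition(self):
        part = shared_unique({"1", "2", "3"}, {"2", "3", "4"})
        assert part.unique_a == {"1"}
        assert part.shared == {"2", "3"}
        assert part.unique_b == {"4"}

    def test_disjoint_sets_share_nothing(self):
        part = shared_unique({"a"}, {"b"})
        assert part.shared == frozenset()

    @given(
        a=st.sets(st.integers(0, 199), max_size=200),
        b=st.sets(st.integers(0, 199), max_size=200),
    )
    @settings(max_examples=100, deadline=None)
    def test_compartments_partition_the_union(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        part = shared_unique(a, b)
        assert len(part.unique_a) + len(part.shared) + len(part.unique_b) == len(a | b)
        assert part.unique_a | part.shared | part.unique_b == a | b
        for x, y in ((part.unique_a, part.shared), (part.unique_a, part.unique_b), (part.shared, part.unique_b)):
            assert not (x & y)


class TestSaturation:
    def test_curve_equals_prefix_oracle(self, small_cohort, small_cohort_matrix):
        m = small_cohort_matrix
        order = small_cohort.control_ids
        read_counts = {sid: len(r) for sid, r in small_cohort.samples.items()}
        points = saturation_curve(m, small_cohort.case_ids, order, read_counts)
        assert len(points) == len(order)
        cumulative = 0
        for k, point in enumerate(points, start=1):
            cumulative += read_counts[order[k - 1]]
            expected = unique_case_loci(m, order[:k], small_cohort.case_ids)
            assert point.n_case_unique_loci == len(expected)
            assert point.cumulative_control_reads == cumulative
        counts = [p.n_case_unique_loci for p in points]
        assert counts == sorted(counts, reverse=True)

    def test_zero_positive_control_leaves_count_unchanged(self):
        samples = [
            _sample("c1", {"L1": "negative", "L2": "positive"}),
            _sample("c2", {"L1": "negative", "L2": "negative"}),  # no positives
            _sample("k1", {"L1": "positive", "L2": "positive"}),
        ]
        m = build_presence_matrix(samples)
        points = saturation_curve(m, ["k1"], ["c1", "c2"], {"c1": 100, "c2": 50})
        assert points[0].n_case_unique_loci == points[1].n_case_unique_loci == 1


class TestSubsampling:
    def _reads(self, n=1000):
        return [AlignedRead(f"r{i}", "L1", 0, "ACGT", 0) for i in range(n)]

    def test_full_sample_is_identity(self):
        reads = self._reads(50)
        assert subsample_reads(reads, 50, seed=1) == reads

    def test_zero_sample_is_empty(self):
        assert subsample_reads(self._reads(10), 0, seed=1) == []

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_reads(self._reads(10), 11, seed=1)

    def test_seed_determinism_and_seed_sensitivity(self):
        reads = self._reads(1000)
        a = subsample_reads(reads, 400, seed=9)
        b = subsample_reads(reads, 400, seed=9)
        c = subsample_reads(reads, 400, seed=10)
        assert a == b
        assert [r.read_id for r in a] != [r.read_id for r in c]
        # order-preserving, no replacement
        ids = [r.read_id for r in a]
        assert len(set(ids)) == 400
        assert ids == [r.read_id for r in reads if r.read_id in set(ids)]


class TestDepthRankTest:
    def test_separated_triplets_exact_p(self):
        res = depth_rank_test([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_singleton_vs_four(self):
        res = depth_rank_test([5], [1, 2, 3, 4])
        assert res.u_statistic == 4.0
        assert res.p_value == pytest.approx(0.4)

    def test_identical_samples_p_one(self):
        res = depth_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            depth_rank_test([], [1.0])

    def test_ties_or_large_n_use_corrected_normal_approximation(self):
        assert depth_rank_test([1, 1, 2], [2, 3, 4]).method == "asymptotic"
        big = list(range(20))
        assert depth_rank_test(big, [x + 0.5 for x in big]).method == "asymptotic"

    @pytest.mark.parametrize("n,m", [(1, 4), (2, 5), (3, 3), (4, 4), (5, 6), (7, 7)])
    def test_exact_branch_agrees_with_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(100 * n + m)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1, n + m + 1, dtype=float))
            x, y = list(pooled[:n]), list(pooled[n:])
            res = depth_rank_test(x, y)
            u_oracle, p_oracle = exact_mannwhitney(x, y)
            assert res.u_statistic == u_oracle
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


class TestFlagSignificantLoci:
    def _matrix_with_depths(self, case_depths, control_depths, case_calls):
        samples = []
        for i, d in enumerate(control_depths):
            scores = {"L1": LocusScore("L1", d, 10, 10, 10, "negative")}
            samples.append(SampleCalls(f"c{i}", "control", scores=scores))
        for i, (d, call) in enumerate(zip(case_depths, case_calls)):
            scores = {"L1": LocusScore("L1", d, 10, 10, 10, call)}
            samples.append(SampleCalls(f"k{i}", "case", scores=scores))
        return build_presence_matrix(samples), [f"c{i}" for i in range(len(control_depths))], [
            f"k{i}" for i in range(len(case_depths))
        ]

    def test_single_case_positive_not_tested(self):
        m, controls, cases = self._matrix_with_depths(
            [9.0, 1.0], [1.5, 2.5, 3.5], ["positive", "negative"]
        )
        table = flag_significant_loci(m, controls, cases)
        assert not table.loc["L1", "tested"]
        assert table.loc["L1", "method"] == "not tested"

    def test_three_vs_three_full_separation_not_significant(self):
        m, controls, cases = self._matrix_with_depths(
            [10.0, 11.0, 12.0], [1.0, 2.0, 3.0], ["positive"] * 3
        )
        table = flag_significant_loci(m, controls, cases)
        assert table.loc["L1", "p"] == pytest.approx(0.1)
        assert not table.loc["L1", "significant"]

    def test_large_shift_flagged_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(55)
        case_d = list(rng.normal(30, 1, size=6))
        ctrl_d = list(rng.normal(3, 1, size=21))
        m, controls, cases = self._matrix_with_depths(case_d, ctrl_d, ["positive"] * 6)
        table = flag_significant_loci(m, controls, cases)
        assert table.loc["L1", "significant"]
        # permutation oracle on the same data
        pooled = np.array(case_d + ctrl_d)
        n = len(case_d)
        u_obs = sum(1 for a in case_d for b in ctrl_d if a > b)
        center = n * len(ctrl_d) / 2
        hits = 0
        for _ in range(10_000):
            perm = rng.permutation(pooled)
            u = int((perm[:n, None] > perm[None, n:]).sum())
            if abs(u - center) >= abs(u_obs - center):
                hits += 1
        p_perm = hits / 10_000
        assert table.loc["L1", "p"] == pytest.approx(p_perm, abs=0.01)

    def test_bh_column_does_not_change_flag(self):
        m, controls, cases = self._matrix_with_depths(
            [10.0, 11.0, 12.0], [1.0, 2.0, 3.0], ["positive"] * 3
        )
        table = flag_significant_loci(m, controls, cases)
        assert "p_bh" in table.columns
        assert table.loc["L1", "p_bh"] >= table.loc["L1", "p"]
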