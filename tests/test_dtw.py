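"""DTW engine: step-pattern registry, DP vs. exhaustive oracle, both modes."""

import numpy as np
import pytest

from trajalign import (
    AlignmentError,
    DissimilarityMatrix,
    STEP_PATTERNS,
    ValidationError,
    cross_dissimilarity,
    enumerate_paths_oracle,
    get_step_pattern,
    global_align,
    local_align,
)

from conftest import make_trajectory

ALL_PATTERNS = sorted(STEP_PATTERNS)


def dmat(values):
    return DissimilarityMatrix(np.asarray(values, dtype=float))


class TestRegistry:
    def test_symmetric2_table(self):
        pat = get_step_pattern("symmetric2")
        assert pat.normalization == "N+M"
        moves = {(p.di, p.dj): p.charges for p in pat.productions}
        assert moves[(1, 1)] == ((0, 0, 2.0),)
        assert moves[(1, 0)] == ((0, 0, 1.0),)
        assert moves[(0, 1)] == ((0, 0, 1.0),)

    def test_asymmetric_table(self):
        pat = get_step_pattern("asymmetric")
        assert pat.normalization == "N"
        assert {(p.di, p.dj) for p in pat.productions} == {(1, 0), (1, 1), (1, 2)}
        assert all(p.charges == ((0, 0, 1.0),) for p in pat.productions)

    def test_p01_alias_resolves_to_p1(self):
        assert get_step_pattern("symmetricP01") is get_step_pattern("symmetricP1")

    def test_unknown_name_lists_registry(self):
        with pytest.raises(AlignmentError, match="symmetric2"):
            get_step_pattern("nosuch")

    @pytest.mark.parametrize("name", ALL_PATTERNS)
    def test_no_zero_displacement_productions(self, name):
        assert all(
            (p.di, p.dj) != (0, 0) for p in STEP_PATTERNS[name].productions
        )


class TestCrossDissimilarity:
    def test_self_matrix_has_zero_diagonal(self, tiny_trajectory):
        d = cross_dissimilarity(tiny_trajectory, tiny_trajectory)
        assert np.allclose(np.diagonal(d.values), 0.0)

    def test_single_pair_equals_bray_curtis(self):
        from trajalign import bray_curtis

        a = make_trajectory([1.0], [[0.7, 0.3, 0.0]], "A")
        b = make_trajectory([1.0], [[0.2, 0.3, 0.5]], "B")
        d = cross_dissimilarity(a, b)
        assert d.values[0, 0] == pytest.approx(0.5)
        assert d.values[0, 0] == pytest.approx(bray_curtis(a.samples[0], b.samples[0]))

    def test_mismatched_features_rejected(self, tiny_trajectory):
        other = make_trajectory([1.0], [[1.0, 0.0, 0.0]], "B", ["x", "y", "z"])
        with pytest.raises(ValidationError, match="feature sets"):
            cross_dissimilarity(tiny_trajectory, other)


class TestGlobalAlign:
    def test_worked_two_by_two_example(self):
        # candidate paths: diagonal 1 + 2*1 = 3; via (1,2): 1+2+1 = 4;
        # via (2,1): 1+3+1 = 5 -> optimum 3, normalized 3/(2+2)
        aln = global_align(dmat([[1, 2], [3, 1]]))
        assert aln.accumulated == pytest.approx(3.0)
        assert aln.normalized == pytest.approx(0.75)
        assert aln.path == [(1, 1), (2, 2)]

    def test_zero_matrix_scores_zero(self):
        aln = global_align(dmat(np.zeros((3, 5))))
        assert aln.accumulated == 0.0 and aln.normalized == 0.0

    def test_self_alignment_is_zero_along_diagonal(self, tiny_trajectory):
        d = cross_dissimilarity(tiny_trajectory, tiny_trajectory)
        aln = global_align(d)
        assert aln.normalized == pytest.approx(0.0)
        assert aln.path == [(1, 1), (2, 2), (3, 3)]

    def test_symmetric2_score_symmetric_in_arguments(self, rng):
        vals = rng.uniform(size=(5, 7))
        a = global_align(dmat(vals))
        b = global_align(dmat(vals.T))
        assert a.accumulated == pytest.approx(b.accumulated)
        assert a.normalized == pytest.approx(b.normalized)

    def test_cost_at_most_pure_diagonal(self, rng):
        for _ in range(20):
            vals = rng.uniform(size=(6, 6))
            diag = vals[0, 0] + 2 * np.diagonal(vals)[1:].sum()
            assert global_align(dmat(vals)).accumulated <= diag + 1e-12

    @pytest.mark.parametrize("name", ALL_PATTERNS)
    def test_scaling_d_scales_costs(self, rng, name):
        vals = rng.uniform(size=(4, 4))
        pat = STEP_PATTERNS[name]
        base = global_align(dmat(vals), pat)
        scaled = global_align(dmat(2.5 * vals), pat)
        assert scaled.accumulated == pytest.approx(2.5 * base.accumulated)
        assert scaled.normalized == pytest.approx(2.5 * base.normalized)

    def test_unreachable_under_slope_constraint(self):
        # symmetricP2 advances at most 3 rows per 2 columns: 2x8 is impossible
        with pytest.raises(AlignmentError, match="no admissible"):
            global_align(dmat(np.ones((2, 8))), STEP_PATTERNS["symmetricP2"])

    @pytest.mark.parametrize("name", ALL_PATTERNS)
    def test_paths_are_weakly_monotone(self, rng, name):
        for _ in range(10):
            n, m = rng.integers(2, 7, size=2)
            try:
                aln = global_align(dmat(rng.uniform(size=(n, m))), STEP_PATTERNS[name])
            except AlignmentError:
                continue
            xs, ys = zip(*aln.path)
            assert all(a <= b for a, b in zip(xs, xs[1:]))
            assert all(a <= b for a, b in zip(ys, ys[1:]))
            assert aln.path[0] == (1, 1) and aln.path[-1] == (n, m)


class TestLocalAlign:
    def test_worked_two_by_four_example(self):
        aln = local_align(dmat([[0.9, 0.1, 0.2, 0.9], [0.9, 0.8, 0.1, 0.9]]))
        assert aln.accumulated == pytest.approx(0.2)
        assert aln.normalized == pytest.approx(0.1)
        assert aln.path == [(1, 2), (2, 3)]
        assert aln.matched_reference_window == (2, 3)

    def test_noise_free_subwindow_recovered(self, rng):
        ref = rng.dirichlet(np.ones(4), size=8)
        query = ref[3:6]
        d = np.full((3, 8), 0.4)
        for i in range(3):
            d[i, 3 + i] = 0.0
        aln = local_align(dmat(d))
        assert aln.normalized == pytest.approx(0.0)
        assert aln.matched_reference_window == (4, 6)

    def test_single_sample_query_takes_best_reference_match(self):
        aln = local_align(dmat([[0.5, 0.2, 0.9]]))
        assert aln.normalized == pytest.approx(0.2)
        assert aln.path == [(1, 2)]

    def test_query_rows_each_matched_once(self, rng):
        d = rng.uniform(size=(4, 7))
        aln = local_align(dmat(d))
        assert sorted({i for i, _ in aln.path}) == [1, 2, 3, 4]

    def test_non_n_normalized_pattern_rejected(self):
        with pytest.raises(AlignmentError, match="open-begin"):
            local_align(dmat(np.ones((2, 2))), STEP_PATTERNS["symmetric2"])


class TestOracleEquivalence:
    def test_one_by_one(self):
        cost, path = enumerate_paths_oracle(dmat([[0.7]]), STEP_PATTERNS["symmetric2"])
        assert cost == pytest.approx(0.7) and path == [(1, 1)]

    def test_guard_on_large_matrices(self, rng):
        with pytest.raises(ValidationError, match="guard"):
            enumerate_paths_oracle(dmat(rng.uniform(size=(8, 3))), STEP_PATTERNS["symmetric2"])

    @pytest.mark.parametrize("name", ALL_PATTERNS)
    def test_global_dp_matches_enumeration(self, name):
        rng = np.random.default_rng(7)
        pat = STEP_PATTERNS[name]
        for _ in range(40):
            n, m = rng.integers(2, 7, size=2)
            d = dmat(rng.uniform(size=(n, m)))
            oracle_cost, _ = enumerate_paths_oracle(d, pat, "global")
            try:
                aln = global_align(d, pat)
            except AlignmentError:
                assert not np.isfinite(oracle_cost)
                continue
            assert aln.accumulated == pytest.approx(oracle_cost)

    def test_local_dp_matches_enumeration(self):
        rng = np.random.default_rng(11)
        pat = STEP_PATTERNS["asymmetric"]
        for _ in range(40):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 8))
            d = dmat(rng.uniform(size=(n, m)))
            oracle_cost, _ = enumerate_paths_oracle(d, pat, "open-begin-end")
            assert local_align(d, pat).accumulated == pytest.approx(oracle_cost)
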