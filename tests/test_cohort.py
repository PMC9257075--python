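"""Trajectory splits, shuffling, Mann-Whitney, PERMANOVA."""

import itertools

import numpy as np
import pytest

from trajalign import (
    TrajectoryDissimilarityMatrix,
    ValidationError,
    crop_trajectory,
    mann_whitney,
    permanova,
    shuffle_trajectory,
    split_halves,
    split_odd_even,
)

from conftest import make_trajectory


def traj_of_length(n, seed=0, subject="S"):
    rng = np.random.default_rng(seed)
    return make_trajectory(
        np.arange(n) * 30.0 + 10.0, rng.dirichlet(np.ones(4), size=n), subject
    )


class TestShuffle:
    def test_seed_reproducible_and_rows_preserved(self):
        traj = traj_of_length(8)
        a = shuffle_trajectory(traj, 5)
        b = shuffle_trajectory(traj, 5)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.times, traj.times)
        assert np.allclose(np.sort(a.samples, axis=0), np.sort(traj.samples, axis=0))

    def test_two_samples_identity_or_swap(self):
        traj = traj_of_length(2)
        out = shuffle_trajectory(traj, 1)
        same = np.allclose(out.samples, traj.samples)
        swapped = np.allclose(out.samples, traj.samples[::-1])
        assert same or swapped


class TestSplits:
    @pytest.mark.parametrize("n, early, late", [(4, 2, 2), (5, 3, 2), (2, 1, 1)])
    def test_halves_ceiling_rule(self, n, early, late):
        a, b = split_halves(traj_of_length(n))
        assert (a.n_samples, b.n_samples) == (early, late)
        assert a.times[-1] < b.times[0]

    @pytest.mark.parametrize("n, odd, even", [(6, 3, 3), (3, 2, 1), (2, 1, 1)])
    def test_odd_even_partition(self, n, odd, even):
        traj = traj_of_length(n)
        a, b = split_odd_even(traj)
        assert (a.n_samples, b.n_samples) == (odd, even)
        assert a.times[0] == traj.times[0]  # "odd" gets the first sample
        union = np.sort(np.concatenate([a.times, b.times]))
        assert np.array_equal(union, traj.times)

    def test_crop_keeps_inclusive_window(self):
        traj = traj_of_length(5)  # times 10..130
        out = crop_trajectory(traj, 40, 100)
        assert list(out.times) == [40.0, 70.0, 100.0]
        with pytest.raises(ValidationError, match="removed all"):
            crop_trajectory(traj, 500, 600)


class TestMannWhitney:
    def test_exact_small_sample_case(self):
        # all 6 rank assignments equally likely; [1,2] vs [3,4] is one of
        # the two extremes -> two-sided p = 2/6
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_symmetric_in_group_order(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.0, size=12)
        _, p1 = mann_whitney(a, b)
        _, p2 = mann_whitney(b, a)
        assert p1 == pytest.approx(p2)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_same_distribution_not_significant(self):
        vals = list(range(10))
        _, p = mann_whitney(vals, vals)
        assert p > 0.9


def square_matrix(values, ids):
    return TrajectoryDissimilarityMatrix(ids, np.asarray(values, dtype=float), "aligned")


TOY4 = np.array(
    [
        [0.0, 0.2, 0.8, 0.7],
        [0.2, 0.0, 0.9, 0.6],
        [0.8, 0.9, 0.0, 0.3],
        [0.7, 0.6, 0.3, 0.0],
    ]
)


def permanova_f_oracle(d, groups):
    """Direct transcription of the pseudo-F definition, independent of the
    package implementation."""
    d = np.asarray(d, float)
    n = len(groups)
    labels = sorted(set(groups))
    a = len(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for lab in labels:
        members = [i for i, g in enumerate(groups) if g == lab]
        ss_within += sum(
            d[i, j] ** 2 for i in members for j in members if i < j
        ) / len(members)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_statistic_matches_direct_formula_and_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")

        mat = square_matrix(TOY4, list("ABCD"))
        labels = {"A": "x", "B": "x", "C": "y", "D": "y"}
        f, _ = permanova(mat, labels, n_perm=9, seed=0)
        assert f == pytest.approx(permanova_f_oracle(TOY4, ["x", "x", "y", "y"]))
        res = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(TOY4, list("ABCD")),
            grouping=["x", "x", "y", "y"],
            permutations=9,
        )
        assert f == pytest.approx(res["test statistic"])

    def test_sampled_p_within_monte_carlo_error_of_exhaustive(self):
        mat = square_matrix(TOY4, list("ABCD"))
        labels = {"A": "x", "B": "x", "C": "y", "D": "y"}
        f_obs = permanova_f_oracle(TOY4, ["x", "x", "y", "y"])
        base = np.array(["x", "x", "y", "y"])
        exact = np.mean(
            [
                permanova_f_oracle(TOY4, list(p)) >= f_obs
                for p in itertools.permutations(base)
            ]
        )
        n_perm = 999
        _, p = permanova(mat, labels, n_perm=n_perm, seed=12345)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 3 * se + 2 / (n_perm + 1)

    def test_perfect_block_structure_reaches_minimal_p(self):
        n = 24
        vals = np.ones((n, n))
        vals[:12, :12] = 0.0
        vals[12:, 12:] = 0.0
        np.fill_diagonal(vals, 0.0)
        ids = [f"S{i}" for i in range(n)]
        mat = square_matrix(vals, ids)
        labels = {s: ("a" if i < 12 else "b") for i, s in enumerate(ids)}
        _, p = permanova(mat, labels, n_perm=999, seed=7)
        assert p == pytest.approx(1 / 1000)

    def test_equal_distances_give_p_one(self):
        n = 6
        vals = np.full((n, n), 0.4)
        np.fill_diagonal(vals, 0.0)
        ids = [f"S{i}" for i in range(n)]
        mat = square_matrix(vals, ids)
        labels = {s: ("a" if i < 3 else "b") for i, s in enumerate(ids)}
        _, p = permanova(mat, labels, n_perm=99, seed=0)
        assert p == 1.0

    def test_invariant_to_category_renaming(self):
        mat = square_matrix(TOY4, list("ABCD"))
        p1 = permanova(mat, {"A": "x", "B": "x", "C": "y", "D": "y"}, seed=4)[1]
        p2 = permanova(mat, {"A": "left", "B": "left", "C": "right", "D": "right"}, seed=4)[1]
        assert p1 == p2

    def test_singleton_category_rejected(self):
        mat = square_matrix(TOY4, list("ABCD"))
        with pytest.raises(ValidationError, match=">= 2 subjects"):
            permanova(mat, {"A": "x", "B": "x", "C": "x", "D": "y"})
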