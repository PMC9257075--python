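"""Cohort-level experiments and statistics on alignment scores.

Three experiment designs probe whether alignment scores carry temporal
signal:

* **shuffle** — pairwise aligned scores of the original interpolated
  trajectories against scores after randomly permuting each trajectory's
  sample order (times kept fixed). Alignment can only exploit monotone
  structure, so shuffling should worsen (raise) the scores.
* **halves** — each trajectory is split into an early and a late half;
  early-early and late-late alignments should score better than early-late
  ones when development follows a shared staged pattern.
* **twins** — each original (non-interpolated) trajectory is split into
  odd- and even-indexed sub-trajectories, which are then interpolated and
  cropped to the first year; same-subject scores should beat twin-pair
  scores, which in turn should beat unrelated-pair scores.

Score groups are compared with the Mann-Whitney rank-sum test; phenotype
partitions of a trajectory dissimilarity matrix are tested with PERMANOVA
(Anderson's permutational MANOVA pseudo-F with a seeded permutation p).
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
from scipy import stats

from .dissimilarity import TrajectoryDissimilarityMatrix, pairwise_matrix, trajectory_dissimilarity
from .dtw import StepPattern, asymmetric, cross_dissimilarity, global_align, symmetric2
from .interpolation import InterpolationParams, interpolate_trajectory, make_grid
from .io import Trajectory, ValidationError

logger = logging.getLogger("trajalign")

#: group name -> list of trajectory-dissimilarity values
GroupedScores = dict


# ---------------------------------------------------------------------------
# Trajectory manipulations
# ---------------------------------------------------------------------------

def shuffle_trajectory(traj: Trajectory, seed) -> Trajectory:
    """Permute the sample compositions uniformly at random over the fixed
    time slots (the time vector is unchanged)."""
    if traj.n_samples < 2:
        raise ValidationError("shuffling needs >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(traj.n_samples)
    return Trajectory(traj.subject_id, traj.times, traj.samples[perm], traj.feature_ids)


def split_halves(traj: Trajectory) -> tuple[Trajectory, Trajectory]:
    """First ceil(n/2) samples -> early half, remainder -> late half."""
    if traj.n_samples < 2:
        raise ValidationError("splitting needs >= 2 samples")
    k = math.ceil(traj.n_samples / 2)
    idx = np.arange(traj.n_samples)
    return (
        traj.subset(idx[:k], f"{traj.subject_id}/early"),
        traj.subset(idx[k:], f"{traj.subject_id}/late"),
    )


def split_odd_even(traj: Trajectory) -> tuple[Trajectory, Trajectory]:
    """Alternating split by chronological index (1-based; "odd" gets the
    first sample). Apply to original, non-interpolated trajectories."""
    if traj.n_samples < 2:
        raise ValidationError("splitting needs >= 2 samples")
    idx = np.arange(traj.n_samples)
    return (
        traj.subset(idx[0::2], f"{traj.subject_id}/odd"),
        traj.subset(idx[1::2], f"{traj.subject_id}/even"),
    )


def crop_trajectory(traj: Trajectory, t_min: float, t_max: float) -> Trajectory:
    """Restrict a trajectory to samples with t_min <= time <= t_max."""
    keep = np.flatnonzero((traj.times >= t_min) & (traj.times <= t_max))
    if keep.size == 0:
        raise ValidationError(
            f"{traj.subject_id}: cropping to [{t_min}, {t_max}] removed all samples"
        )
    return traj.subset(keep)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney rank-sum test; returns (U statistic of the first group,
    p-value). Exact for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney requires two nonempty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney: all values identical; returning p = 1")
        return float(a.size * b.size / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def _permanova_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from squared dissimilarities and integer labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    cats = np.unique(groups)
    for c in cats:
        members = np.flatnonzero(groups == c)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += np.triu(sub, k=1).sum() / members.size
    a = cats.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else math.nan
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    matrix: TrajectoryDissimilarityMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA on a trajectory dissimilarity matrix.

    ``labels`` maps subject id -> category; subjects absent from the
    mapping are excluded. The pseudo-F uses squared dissimilarities
    (SS_total = sum_{i<j} d_ij^2 / N; SS_within pooled per group divided by
    group size) and the p-value is (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    over seeded uniform permutations of the label vector.
    """
    keep = [i for i, s in enumerate(matrix.subject_ids) if s in labels]
    if len(keep) < 4:
        raise ValidationError("permanova needs >= 4 labelled subjects")
    sub = matrix.values[np.ix_(keep, keep)]
    if not np.isfinite(sub).all():
        raise ValidationError("permanova requires no missing cells among tested subjects")
    cats_raw = [labels[matrix.subject_ids[i]] for i in keep]
    cat_names, groups = np.unique(cats_raw, return_inverse=True)
    if cat_names.size < 2:
        raise ValidationError("permanova needs >= 2 categories")
    counts = np.bincount(groups)
    if (counts < 2).any():
        small = cat_names[np.flatnonzero(counts < 2)]
        raise ValidationError(f"every category needs >= 2 subjects; too small: {list(small)}")

    d2 = sub**2
    f_obs = _permanova_f(d2, groups)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(groups)) >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# Experiment battery
# ---------------------------------------------------------------------------

def shuffle_experiment(
    interpolated,
    pattern: StepPattern = symmetric2,
    seed: int = 0,
) -> GroupedScores:
    """Pairwise aligned scores of a cohort vs. the same cohort with each
    trajectory's temporal order shuffled."""
    interpolated = list(interpolated)
    rng = np.random.default_rng(seed)
    shuffled = [shuffle_trajectory(t, rng) for t in interpolated]
    orig = pairwise_matrix(interpolated, method="aligned", pattern=pattern)
    shuf = pairwise_matrix(shuffled, method="aligned", pattern=pattern)
    return {
        "original": list(orig.condensed()),
        "shuffled": list(shuf.condensed()),
    }


def halves_experiment(
    interpolated,
    pattern: StepPattern = symmetric2,
) -> GroupedScores:
    """Global alignment scores between early halves, late halves, and
    early-vs-late halves across all subject pairs.

    Halves are aligned directly (no overlap trimming): an early and a late
    half cover disjoint calendar windows by construction, and DTW compares
    their compositional sequences, not their clocks.
    """
    interpolated = [t for t in interpolated if t.n_samples >= 2]
    halves = [split_halves(t) for t in interpolated]

    def score(x: Trajectory, y: Trajectory) -> float:
        return float(global_align(cross_dissimilarity(x, y), pattern).normalized)

    out: GroupedScores = {"early-early": [], "late-late": [], "early-late": []}
    for (ea, la), (eb, lb) in combinations(halves, 2):
        out["early-early"].append(score(ea, eb))
        out["late-late"].append(score(la, lb))
        out["early-late"].append(score(ea, lb))
        out["early-late"].append(score(eb, la))
    return out


def twin_experiment(
    originals,
    twin_pairs,
    params: InterpolationParams = InterpolationParams(),
    crop: tuple = (0.0, 365.0),
    pattern: StepPattern = symmetric2,
) -> GroupedScores:
    """Same-subject vs. twin vs. unrelated aligned scores.

    Each original trajectory is split alternately into odd/even-indexed
    sub-trajectories, each sub-trajectory interpolated (default 30-day
    grid, window 30) and cropped to ``crop`` (the first year by default).
    Scores are then computed between every pair of sub-trajectories and
    grouped by the relationship of their source subjects. ``twin_pairs``
    is an iterable of (subject_id, subject_id) tuples.
    """
    twin_lookup = {frozenset(p) for p in twin_pairs}
    subs: dict[str, list[Trajectory]] = {}
    for traj in originals:
        if traj.n_samples < 2:
            logger.warning("subject %s too short for odd/even split; skipped", traj.subject_id)
            continue
        pieces = []
        for piece in split_odd_even(traj):
            if make_grid(piece.times, params).size == 0:
                logger.warning("sub-trajectory %s spans < one interval; excluded", piece.subject_id)
                continue
            piece = interpolate_trajectory(piece, params)
            try:
                piece = crop_trajectory(piece, *crop)
            except ValidationError:
                logger.warning("sub-trajectory %s emptied by cropping; excluded", piece.subject_id)
                continue
            pieces.append(piece)
        if pieces:
            subs[traj.subject_id] = pieces

    out: GroupedScores = {"same-subject": [], "twin": [], "unrelated": []}
    subjects = sorted(subs)
    for s in subjects:
        if len(subs[s]) == 2:
            out["same-subject"].append(
                trajectory_dissimilarity(subs[s][0], subs[s][1], "aligned", pattern)
            )
    for sa, sb in combinations(subjects, 2):
        group = "twin" if frozenset((sa, sb)) in twin_lookup else "unrelated"
        for x in subs[sa]:
            for y in subs[sb]:
                try:
                    out[group].append(trajectory_dissimilarity(x, y, "aligned", pattern))
                except ValidationError:
                    logger.warning("no overlap between %s and %s", x.subject_id, y.subject_id)
    return out
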