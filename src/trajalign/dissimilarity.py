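"""Sample-level Bray-Curtis and trajectory-level dissimilarity methods.

Three trajectory-level methods are provided, all computed on interpolated,
overlap-trimmed trajectory pairs:

* ``aligned``  — the normalized global DTW alignment score;
* ``diagonal`` — the mean dissimilarity between chronologically parallel
  samples (the naive baseline that ignores pace differences);
* ``min``      — the smallest pairwise sample dissimilarity (a baseline
  that ignores temporal structure altogether).

Bray-Curtis is used as the sample-level metric throughout. Note that
Bray-Curtis is bounded in [0, 1] and symmetric but does not satisfy the
triangle inequality, so none of the trajectory-level quantities is a
metric either; they are dissimilarities suitable for ranking, ordination
and permutation tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw import AlignmentError, StepPattern, cross_dissimilarity, global_align, symmetric2
from .io import Trajectory, ValidationError, trim_to_overlap

logger = logging.getLogger("trajalign")

METHODS = ("aligned", "diagonal", "min")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x, y)) / (sum(x) + sum(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bray_curtis expects two 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("bray_curtis requires non-negative entries")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("bray_curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def trajectory_dissimilarity(
    a: Trajectory,
    b: Trajectory,
    method: str = "aligned",
    pattern: StepPattern = symmetric2,
    metric: str = "bray-curtis",
) -> float:
    """Single dissimilarity between two trajectories under one method.

    The pair is first trimmed to its shared time points (the trajectories
    are expected to be interpolated onto the common grid convention), after
    which the chosen method is applied to the pairwise sample
    dissimilarities.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; known: {METHODS}")
    ta, tb = trim_to_overlap(a, b)
    d = cross_dissimilarity(ta, tb, metric=metric)
    if method == "aligned":
        return float(global_align(d, pattern).normalized)
    if method == "diagonal":
        return float(np.diagonal(d.values).mean())
    return float(d.values.min())


@dataclass
class TrajectoryDissimilarityMatrix:
    """Subject-by-subject trajectory dissimilarities under one method.

    Pairs with no shared time points are missing (NaN) and excluded from
    downstream statistics.
    """

    subject_ids: list
    values: np.ndarray
    method: str
    step_pattern: str | None = None

    def __post_init__(self) -> None:
        self.subject_ids = list(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.subject_ids)
        if self.values.shape != (k, k):
            raise ValidationError("trajectory dissimilarity matrix must be square")
        finite = self.values[np.isfinite(self.values)]
        if (finite < 0).any():
            raise ValidationError("dissimilarities must be >= 0")
        asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-10:
            raise ValidationError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.subject_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (i < j), NaN pairs dropped."""
        iu = np.triu_indices(len(self.subject_ids), k=1)
        vals = self.values[iu]
        return vals[np.isfinite(vals)]


def pairwise_matrix(
    cohort,
    method: str = "aligned",
    pattern: StepPattern = symmetric2,
    metric: str = "bray-curtis",
) -> TrajectoryDissimilarityMatrix:
    """Evaluate all unordered trajectory pairs of a cohort.

    The diagonal is zero by definition; pairs without shared time points
    are recorded as missing with a logged count.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValidationError("pairwise_matrix needs >= 2 trajectories")
    k = len(cohort)
    vals = np.zeros((k, k))
    n_missing = 0
    for i in range(k):
        for j in range(i + 1, k):
            try:
                v = trajectory_dissimilarity(
                    cohort[i], cohort[j], method=method, pattern=pattern, metric=metric
                )
            except (ValidationError, AlignmentError):
                v = np.nan
                n_missing += 1
            vals[i, j] = vals[j, i] = v
    if n_missing:
        logger.warning(
            "%d trajectory pairs had no shared time points or no admissible path",
            n_missing,
        )
    return TrajectoryDissimilarityMatrix(
        [t.subject_id for t in cohort], vals, method, pattern.name
    )
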