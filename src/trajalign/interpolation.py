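"""Gaussian-kernel resampling of irregular trajectories onto an even grid.

Longitudinal microbiome cohorts are sampled unevenly, so trajectories are
resampled onto a shared even grid before alignment. Each interpolated value
is a Gaussian-weighted average of the original samples,

    f(t) = sum_i w_i * f_i / sum_i w_i,    w_i = exp(-(t - t_i)^2 / window^2),

where ``window`` (days) controls how strongly nearby original samples
dominate remote ones. All original samples contribute (there is no
truncation radius); the window sets the effective locality. Interpolated
rows are re-normalized to relative abundances.

The grid starts at the first multiple of ``interval_days`` strictly greater
than the earliest original sample and ends at the last multiple not
exceeding the latest one, so interpolated trajectories from different
subjects land on comparable time points without extrapolating beyond the
observed range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Trajectory, ValidationError

logger = logging.getLogger("trajalign")

#: below this total kernel mass a grid point is considered unreachable
_MIN_WEIGHT_SUM = 1e-300


@dataclass(frozen=True)
class InterpolationParams:
    """Grid spacing and kernel bandwidth, both in days (defaults 30/30)."""

    interval_days: float = 30.0
    window: float = 30.0

    def __post_init__(self) -> None:
        if self.interval_days <= 0 or self.window <= 0:
            raise ValidationError("interval_days and window must be positive")


def make_grid(times, params: InterpolationParams = InterpolationParams()) -> np.ndarray:
    """Even grid covered by ``times``: multiples of the interval, starting
    strictly after the earliest sample and ending at or before the latest.

    May be empty when the observation span contains no such multiple.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be nonempty")
    step = params.interval_days
    start = (np.floor(times.min() / step) + 1.0) * step
    stop = np.floor(times.max() / step) * step
    if start > stop:
        return np.empty(0)
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def interpolate_trajectory(
    traj: Trajectory, params: InterpolationParams = InterpolationParams()
) -> Trajectory:
    """Resample ``traj`` onto its even grid with the Gaussian kernel.

    Raises if the grid is empty (trajectory shorter than one interval) or
    if a grid point carries numerically zero kernel mass.
    """
    grid = make_grid(traj.times, params)
    if grid.size == 0:
        raise ValidationError(
            f"subject {traj.subject_id}: observation span too short for "
            f"interval {params.interval_days}"
        )
    # weights: grid points x original samples
    w = np.exp(-((grid[:, None] - traj.times[None, :]) ** 2) / params.window**2)
    sums = w.sum(axis=1)
    if (sums < _MIN_WEIGHT_SUM).any():
        t_bad = grid[int(np.argmin(sums))]
        raise ValidationError(
            f"subject {traj.subject_id}: grid point {t_bad} too far from data"
        )
    values = (w @ traj.samples) / sums[:, None]
    # weighted averages of compositions already sum to ~1; renormalize exactly
    values = values / values.sum(axis=1, keepdims=True)
    return Trajectory(traj.subject_id, grid, values, traj.feature_ids)


def interpolate_cohort(
    trajectories, params: InterpolationParams = InterpolationParams()
) -> list[Trajectory]:
    """Interpolate every trajectory, skipping (with a warning) subjects whose
    observation span is shorter than one grid interval."""
    out = []
    for traj in trajectories:
        if make_grid(traj.times, params).size == 0:
            logger.warning(
                "subject %s skipped: span shorter than one interval", traj.subject_id
            )
            continue
        out.append(interpolate_trajectory(traj, params))
    return out
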