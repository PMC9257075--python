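"""Synthetic longitudinal cohorts with known maturation structure.

The generator emulates the statistical structure of infant-gut longitudinal
studies: each subject's expected composition moves along a shared
maturation curve from an infant-like to an adult-like endpoint profile,

    E[x(t)] = (1 - m) * p_infant + m * p_adult,
    m = logistic((u(t) - midpoint) / scale),

where u(t) is a subject-specific monotone time warp: effective time accrues
at a per-subject *pace* (LogNormal across subjects), and — for delayed
subjects — at a reduced rate inside a developmental-stall window. Observed
samples are Dirichlet draws around the expected composition, with a single
concentration parameter as the noise knob, so every generated row is a
valid composition. Twin pairs share family-level endpoint profiles and
pace up to small individual noise. Sampling times start at day 0 and
advance by jittered intervals.

A truth table records every subject's pace, stall and twin pairing so that
recovery can be asserted without re-deriving generative parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleMetadata, Trajectory, ValidationError


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults describe a two-year monthly-sampled cohort of 30 subjects and
    50 features with moderate compositional noise; ``pace_sigma`` is the
    log-scale spread of the per-subject maturation pace, and the stall
    window/factor describe how delayed subjects' effective time slows.
    """

    n_subjects: int = 30
    n_features: int = 50
    n_twin_pairs: int = 0
    n_delayed: int = 0
    follow_up_days: float = 730.0
    sampling_interval_mean: float = 30.0
    sampling_interval_jitter: float = 7.0
    pace_sigma: float = 0.25
    stall_window: tuple = (120.0, 420.0)
    stall_factor: float = 0.15
    noise_concentration: float = 200.0
    logistic_midpoint: float = 365.0
    logistic_scale: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_features, self.n_twin_pairs, self.n_delayed) < 0:
            raise ValidationError("counts must be >= 0")
        if self.n_features < 2:
            raise ValidationError("need at least 2 features")
        if self.n_twin_pairs * 2 + self.n_delayed > self.n_subjects:
            raise ValidationError("twins and delayed subjects exceed cohort size")
        if self.noise_concentration <= 0 or self.pace_sigma < 0:
            raise ValidationError("noise_concentration must be > 0, pace_sigma >= 0")
        if not 0 <= self.stall_factor < 1:
            raise ValidationError("stall_factor must lie in [0, 1)")
        if self.stall_window[1] < self.stall_window[0]:
            raise ValidationError("stall_window must be (start, end) with start <= end")


def warp_time(
    t: float, pace: float, stall_window: tuple = None, stall_factor: float = 1.0
) -> float:
    """Maturation time u(t) = pace * effective elapsed time.

    Inside ``stall_window`` effective time accrues at rate
    ``stall_factor``; u is continuous, non-decreasing and piecewise linear.
    """
    t = float(t)
    if t < 0:
        raise ValidationError("t must be >= 0")
    if stall_window is None:
        return pace * t
    lo, hi = stall_window
    stalled = max(0.0, min(t, hi) - lo)
    effective = t - stalled * (1.0 - stall_factor)
    return pace * effective


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


# family-level endpoint concentration (how distinct families are) and
# twin-level concentration (how close co-twins are to the family profile)
_FAMILY_KAPPA = 50.0
_TWIN_KAPPA = 3000.0
_TWIN_PACE_SIGMA = 0.05


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw guarded against numerically zero components."""
    draw = rng.dirichlet(np.maximum(alpha, 1e-6))
    draw = np.maximum(draw, 1e-12)
    return draw / draw.sum()


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Trajectory], list[SampleMetadata], pd.DataFrame]:
    """Generate a cohort: trajectories, per-sample metadata, truth table.

    Subjects are named S00, S01, ...; the first ``2 * n_twin_pairs`` form
    twin pairs, the last ``n_delayed`` carry the developmental stall.
    Metadata labels include ``group`` ("healthy" or "delayed"). Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_features

    # cohort-level endpoint profiles: sparse-ish infant and adult communities
    p_infant = _dirichlet(rng, np.full(k, 0.6))
    p_adult = _dirichlet(rng, np.full(k, 0.6))

    n = config.n_subjects
    subject_ids = [f"S{i:02d}" for i in range(n)]
    twin_of: dict[int, int] = {}
    for pair in range(config.n_twin_pairs):
        a, b = 2 * pair, 2 * pair + 1
        twin_of[a] = b
        twin_of[b] = a
    delayed = set(range(n - config.n_delayed, n))

    # family-level draws (shared by co-twins)
    endpoints: dict[int, tuple] = {}
    paces: dict[int, float] = {}
    for i in range(n):
        partner = twin_of.get(i)
        if partner is not None and partner in endpoints:
            fam_inf, fam_adu, fam_pace = (
                endpoints[partner][2],
                endpoints[partner][3],
                paces[partner] / endpoints[partner][4],
            )
        else:
            fam_inf = _dirichlet(rng, _FAMILY_KAPPA * p_infant)
            fam_adu = _dirichlet(rng, _FAMILY_KAPPA * p_adult)
            fam_pace = float(rng.lognormal(0.0, config.pace_sigma))
        if i in twin_of:
            own_inf = _dirichlet(rng, _TWIN_KAPPA * fam_inf)
            own_adu = _dirichlet(rng, _TWIN_KAPPA * fam_adu)
            indiv = float(rng.lognormal(0.0, _TWIN_PACE_SIGMA))
        else:
            own_inf, own_adu, indiv = fam_inf, fam_adu, 1.0
        endpoints[i] = (own_inf, own_adu, fam_inf, fam_adu, indiv)
        paces[i] = fam_pace * indiv

    trajectories: list[Trajectory] = []
    metadata: list[SampleMetadata] = []
    truth_rows = []
    feature_ids = [f"F{j:03d}" for j in range(k)]
    for i, sid in enumerate(subject_ids):
        own_inf, own_adu = endpoints[i][0], endpoints[i][1]
        pace = paces[i]
        stall = config.stall_window if i in delayed else None
        stall_factor = config.stall_factor if i in delayed else 1.0

        times = [0.0]
        while True:
            step = config.sampling_interval_mean + rng.uniform(
                -config.sampling_interval_jitter, config.sampling_interval_jitter
            )
            nxt = times[-1] + max(1.0, step)
            if nxt > config.follow_up_days:
                break
            times.append(nxt)
        times = np.asarray(times)

        u = np.array([warp_time(t, pace, stall, stall_factor) for t in times])
        m = _logistic((u - config.logistic_midpoint) / config.logistic_scale)
        expected = (1.0 - m)[:, None] * own_inf[None, :] + m[:, None] * own_adu[None, :]
        observed = np.stack(
            [_dirichlet(rng, config.noise_concentration * row) for row in expected]
        )
        trajectories.append(Trajectory(sid, times, observed, feature_ids))
        group = "delayed" if i in delayed else "healthy"
        for t_idx, t in enumerate(times):
            metadata.append(
                SampleMetadata(
                    sample_id=f"{sid}.{t_idx:03d}",
                    subject_id=sid,
                    age_days=float(t),
                    labels={"group": group},
                )
            )
        truth_rows.append(
            {
                "subject_id": sid,
                "pace": pace,
                "group": group,
                "twin_id": subject_ids[twin_of[i]] if i in twin_of else "",
                "stall_start": stall[0] if stall else np.nan,
                "stall_end": stall[1] if stall else np.nan,
                "stall_factor": stall_factor if stall else np.nan,
                "n_samples": len(times),
            }
        )
    return trajectories, metadata, pd.DataFrame(truth_rows)


def twin_pairs_from_truth(truth: pd.DataFrame) -> list:
    """Unordered twin pairs recorded in a truth table."""
    pairs = set()
    for _, row in truth.iterrows():
        if row["twin_id"]:
            pairs.add(frozenset((row["subject_id"], row["twin_id"])))
    return [tuple(sorted(p)) for p in sorted(pairs, key=sorted)]


def cohort_to_table(trajectories, metadata) -> FeatureTable:
    """Flatten a generated cohort into a FeatureTable matching its metadata."""
    by_subject = {t.subject_id: t for t in trajectories}
    sample_ids, rows = [], []
    counters: dict[str, int] = {}
    for m in metadata:
        traj = by_subject[m.subject_id]
        idx = counters.get(m.subject_id, 0)
        counters[m.subject_id] = idx + 1
        sample_ids.append(m.sample_id)
        rows.append(traj.samples[idx])
    feature_ids = trajectories[0].feature_ids
    return FeatureTable.from_counts(sample_ids, feature_ids, np.stack(rows))
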