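"""Alignment-based age prediction and microbiota-maturity analysis.

A contiguous segment of a trajectory (a *slice*, with its sample ages
hidden) is used as the query of an open-begin-end alignment against every
reference trajectory whose ages are known. The age of a slice sample is
predicted as the unweighted mean of the ages of all reference samples it
was matched to, pooled across references (each matched (reference, sample)
pair counted once). *Relative microbiota maturity* is the predicted minus
the chronological age, so a developmentally delayed (younger-looking)
community has negative maturity.

Age prediction deliberately runs on the original, non-interpolated
trajectories: the exact sample time points are the quantity being
predicted, and interpolation would blur them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import mann_whitney
from .dtw import AlignmentError, StepPattern, asymmetric, cross_dissimilarity, local_align
from .io import Trajectory, ValidationError

logger = logging.getLogger("trajalign")


@dataclass
class Slice:
    """A contiguous sub-segment of a trajectory used as an alignment query.

    ``times`` are carried along for evaluation but are hidden from the
    prediction itself.
    """

    source_subject: str
    start_index: int  # 1-based position within the source trajectory
    length: int
    times: np.ndarray
    samples: np.ndarray
    feature_ids: list

    def prefix(self, length: int) -> "Slice":
        if not 1 <= length <= self.length:
            raise ValidationError(f"prefix length {length} out of range")
        return Slice(
            self.source_subject,
            self.start_index,
            length,
            self.times[:length],
            self.samples[:length],
            self.feature_ids,
        )

    def as_trajectory(self) -> Trajectory:
        return Trajectory(self.source_subject, self.times, self.samples, self.feature_ids)


@dataclass
class AgePredictionRecord:
    """Prediction for one slice sample, with the matched reference samples
    that produced it."""

    subject: str
    sample_time: float
    predicted_age: float
    maturity: float = field(init=False)
    matched: list = field(default_factory=list)  # (reference subject, sample idx, age)

    def __post_init__(self) -> None:
        self.maturity = self.predicted_age - self.sample_time


def extract_slice(traj: Trajectory, start: int, length: int) -> Slice:
    """Contiguous slice of ``length`` samples starting at 1-based ``start``."""
    if length < 1 or start < 1 or start + length - 1 > traj.n_samples:
        raise ValidationError(
            f"slice [{start}, {start + length - 1}] out of range for "
            f"{traj.subject_id} with {traj.n_samples} samples"
        )
    idx = np.arange(start - 1, start - 1 + length)
    return Slice(
        traj.subject_id, start, length, traj.times[idx], traj.samples[idx], traj.feature_ids
    )


def _matched_ages_by_row(d_values: np.ndarray, reference: Trajectory, pattern: StepPattern):
    """Open-begin-end alignment of a query (rows of ``d_values``) inside a
    reference; returns {query row (0-based): [(ref subject, ref idx 1-based,
    ref age), ...]} with each matched pair counted once."""
    from .dtw import DissimilarityMatrix

    aln = local_align(DissimilarityMatrix(d_values, reference.subject_id, "slice"), pattern)
    by_row: dict[int, list] = {}
    seen = set()
    for qi, rj in aln.path:  # 1-based
        if (qi, rj) in seen:
            continue
        seen.add((qi, rj))
        by_row.setdefault(qi - 1, []).append(
            (reference.subject_id, rj, float(reference.times[rj - 1]))
        )
    return by_row


def predict_ages(
    slice_: Slice,
    references,
    targets: str = "first",
    pattern: StepPattern = asymmetric,
) -> list[AgePredictionRecord]:
    """Predict slice sample ages by local alignment against references.

    The slice is aligned (open-begin-end, asymmetric pattern by default) to
    each reference; matched reference samples are pooled across references
    and each target sample's prediction is the unweighted mean of the
    pooled ages. ``targets="first"`` predicts only the first slice sample;
    ``targets="all"`` predicts every sample. References sharing the
    slice's source subject are rejected; references admitting no path are
    skipped with a warning.
    """
    references = list(references)
    if not references:
        raise ValidationError("predict_ages requires at least one reference")
    if targets not in ("first", "all"):
        raise ValidationError(f"targets must be 'first' or 'all', got {targets!r}")
    if any(r.subject_id == slice_.source_subject for r in references):
        raise ValidationError("references must not include the slice's source subject")

    query = slice_.as_trajectory()
    pooled: dict[int, list] = {}
    n_used = 0
    for ref in references:
        d = cross_dissimilarity(query, ref)
        try:
            by_row = _matched_ages_by_row(d.values, ref, pattern)
        except AlignmentError:
            logger.warning(
                "reference %s admits no path for a %d-sample slice; skipped",
                ref.subject_id,
                slice_.length,
            )
            continue
        n_used += 1
        for row, matches in by_row.items():
            pooled.setdefault(row, []).extend(matches)
    if n_used == 0:
        raise AlignmentError("no reference admitted an open-begin-end path")

    rows = [0] if targets == "first" else list(range(slice_.length))
    records = []
    for row in rows:
        matches = pooled.get(row, [])
        if not matches:  # cannot happen under full-query coverage, kept defensive
            raise AlignmentError(f"slice sample {row + 1} matched no reference sample")
        ages = [age for _s, _i, age in matches]
        records.append(
            AgePredictionRecord(
                subject=slice_.source_subject,
                sample_time=float(slice_.times[row]),
                predicted_age=float(np.mean(ages)),
                matched=matches,
            )
        )
    return records


def evaluate_prediction(
    cohort,
    n_iter: int = 300,
    max_len: int = 5,
    seed: int = 0,
    pattern: StepPattern = asymmetric,
) -> pd.DataFrame:
    """Slice-based age-prediction benchmark.

    Per iteration a subject with >= ``max_len`` samples is chosen uniformly
    (with replacement across iterations), a ``max_len``-sample slice start
    is chosen uniformly, and the age of the slice's first sample is
    predicted from all other subjects for every prefix length 1..max_len.
    Returns a frame with Pearson r (and its p-value) and the mean squared
    error per prefix length.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValidationError("evaluate_prediction needs >= 2 subjects")
    eligible = [i for i, t in enumerate(cohort) if t.n_samples >= max_len]
    if not eligible:
        raise ValidationError(f"no subject has >= {max_len} samples")
    rng = np.random.default_rng(seed)

    true_by_len: dict[int, list] = {L: [] for L in range(1, max_len + 1)}
    pred_by_len: dict[int, list] = {L: [] for L in range(1, max_len + 1)}
    for _ in range(n_iter):
        si = eligible[rng.integers(len(eligible))]
        subject = cohort[si]
        start = int(rng.integers(1, subject.n_samples - max_len + 2))
        full = extract_slice(subject, start, max_len)
        refs = [t for t in cohort if t.subject_id != subject.subject_id]
        # one dissimilarity matrix per reference; prefixes reuse its top rows
        d_full = [(ref, cross_dissimilarity(full.as_trajectory(), ref).values) for ref in refs]
        for L in range(1, max_len + 1):
            ages = []
            for ref, dv in d_full:
                try:
                    by_row = _matched_ages_by_row(dv[:L], ref, pattern)
                except AlignmentError:
                    continue
                ages.extend(age for _s, _i, age in by_row.get(0, []))
            if not ages:
                continue
            true_by_len[L].append(float(full.times[0]))
            pred_by_len[L].append(float(np.mean(ages)))

    rows = []
    for L in range(1, max_len + 1):
        t = np.asarray(true_by_len[L])
        p = np.asarray(pred_by_len[L])
        if t.size < 3:
            raise ValidationError(f"too few successful predictions at length {L}")
        r, pval = stats.pearsonr(t, p)
        rows.append(
            {
                "length": L,
                "pearson_r": float(r),
                "p_value": float(pval),
                "mse": float(np.mean((t - p) ** 2)),
                "n": int(t.size),
            }
        )
    return pd.DataFrame(rows)


def maturity_analysis(
    subjects,
    references,
    phase_labels,
    loo_control: bool = False,
    pattern: StepPattern = asymmetric,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phase relative microbiota maturity with pairwise group tests.

    Every sample of every subject trajectory is age-predicted
    (``targets="all"``) against the references; with ``loo_control`` the
    subjects are themselves the reference pool and each is predicted
    against all others (leave-one-out). ``phase_labels`` maps
    ``(subject_id, sample_time)`` to a phase name, or is a callable
    ``(subject_id, sample_time) -> phase``; samples without a phase are
    ignored. Within each subject and phase only the latest sample is
    retained. Returns ``(table, pairwise)`` where ``table`` has one row per
    retained sample (subject, phase, sample_time, predicted_age, maturity)
    and ``pairwise`` holds Mann-Whitney comparisons between phases.
    """
    subjects = list(subjects)
    references = list(references) if references else []
    if loo_control and not references:
        references = subjects
    get_phase = phase_labels if callable(phase_labels) else (
        lambda s, t: phase_labels.get((s, t))
    )

    rows = []
    for traj in subjects:
        # under leave-one-out the subjects are themselves the reference pool;
        # either way a subject never serves as its own reference
        refs = [r for r in references if r.subject_id != traj.subject_id]
        if not refs:
            raise ValidationError(f"no references available for {traj.subject_id}")
        whole = extract_slice(traj, 1, traj.n_samples)
        for rec in predict_ages(whole, refs, targets="all", pattern=pattern):
            phase = get_phase(rec.subject, rec.sample_time)
            if phase is None:
                continue
            rows.append(
                {
                    "subject": rec.subject,
                    "phase": phase,
                    "sample_time": rec.sample_time,
                    "predicted_age": rec.predicted_age,
                    "maturity": rec.maturity,
                }
            )
    if not rows:
        raise ValidationError("no samples carried a phase label")
    table = pd.DataFrame(rows)
    # latest sample per subject and phase
    table = (
        table.sort_values("sample_time")
        .groupby(["subject", "phase"], as_index=False)
        .tail(1)
        .reset_index(drop=True)
    )

    phases = sorted(table["phase"].unique())
    comparisons = []
    for i, pa in enumerate(phases):
        for pb in phases[i + 1 :]:
            va = table.loc[table["phase"] == pa, "maturity"].to_numpy()
            vb = table.loc[table["phase"] == pb, "maturity"].to_numpy()
            if va.size == 0 or vb.size == 0:
                logger.warning("phase %s or %s empty after latest-sample filter", pa, pb)
                continue
            u, p = mann_whitney(va, vb)
            comparisons.append({"phase_a": pa, "phase_b": pb, "U": u, "p_value": p})
    pairwise = pd.DataFrame(comparisons, columns=["phase_a", "phase_b", "U", "p_value"])
    return table, pairwise
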