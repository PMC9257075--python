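# Methods

## Interpolation

Irregularly sampled trajectories are resampled onto an even grid by a
Gaussian kernel: the value of feature f at grid time t is
Σᵢ wᵢ fᵢ / Σᵢ wᵢ with wᵢ = exp(−(t − tᵢ)² / window²). All original samples
contribute — there is no truncation radius — and the window (days) is the
single locality knob. Defaults are a 30-day grid interval and a 30-day
window, a natural scale for monthly-sampled infant cohorts. Rows are
re-normalized to relative abundances after the weighted sum; because a
weighted average of compositions already sums to one, this is a
floating-point correction only, and each interpolated feature value is a
convex combination of the observed values (property-tested).

The grid starts at the first multiple of the interval *strictly greater*
than the earliest observed time and ends at the last multiple not
exceeding the latest, so different subjects' grids are subsets of one
common lattice and no extrapolation beyond the observed span occurs. A
trajectory whose span contains no grid point cannot be interpolated; the
cohort helper skips such subjects with a warning. A grid point whose total
kernel mass underflows (below 1e-300, possible only with windows that are
tiny relative to sampling gaps) is reported as an error rather than
silently renormalized.

## Alignment engine

The DP table D is filled row-major with D(1,1) = d(1,1)·1 — a virtual
origin step with weight one, for every pattern. This makes self-alignment
exactly zero and lets the recurrence agree with a path-enumeration
definition in which the start cell is charged once; the enumeration oracle
in the test suite certifies exactly that equivalence for every registered
pattern on random matrices, including agreement about infeasibility under
the slope-constrained patterns.

Step patterns are configuration data, not code: a list of productions,
each giving the predecessor offset and the charged cells with weights.
symmetric2 charges d(i,j) with weight 2 on the diagonal move and 1 on the
axial moves (normalization n+m); the asymmetric pattern advances the first
axis every step with column moves of 0/1/2 (normalization n); the
slope-constrained symmetric family (P = 1/2, 1, 2) and the type III local
constraint are transcribed from the classical step-pattern literature.
The name `symmetricP01` is accepted as an alias for the P = 1 member,
because that spelling circulates for the same table.

Ties are broken deterministically: productions are scanned in a fixed
priority order (diagonal first, then moves advancing the first axis) and
only strict improvements replace the incumbent, so backtracking is
reproducible. Open-begin-end mode frees the first query row
(D(1,j) = d(1,j) for all j) and minimizes over end columns of the last
query row, taking the smallest column on ties. This mode is restricted to
patterns with per-query-sample ("N") normalization: with a free begin the
matched reference span varies between candidate paths, and only a
normalization that depends on the query alone keeps those candidates
comparable. The asymmetric pattern is the default for local alignment for
the same reason.

Complexity is the standard O(n·m) per pair; all cohort analyses here run
in seconds at desk scale.

## Trajectory dissimilarities and cohort statistics

Trajectory-level dissimilarities (alignment score, diagonal mean, pairwise
minimum) operate on interpolated pairs trimmed to their shared grid
points, so all three methods see the same data; pairs with no shared
points are missing values, never zeros, and are excluded from downstream
statistics with a logged count. Bray-Curtis is the sample-level metric:
bounded in [0,1] and symmetric but *not* a metric (no triangle
inequality), which the permutation-based statistics used here do not
require. The half-comparison experiment aligns early and late halves
directly without trimming — an early and a late half cover disjoint
calendar windows by construction, and DTW compares state sequences, not
clocks.

Mann-Whitney tests default to two-sided (directional hypotheses in the
experiment battery pass `alternative="less"` explicitly); scipy's exact
small-sample path is used when available. PERMANOVA follows Anderson's
formulation on squared dissimilarities with the (1 + exceedances)/(1 +
permutations) convention and a seeded generator. Note that permutations
are drawn uniformly over label arrangements, so any draw preserving the
group partition ties the observed pseudo-F; the minimal attainable p of
1/(n_perm+1) is therefore only observable when group sizes make
partition-preserving draws negligible (with two groups of twelve their
probability is ~7·10⁻⁷; with two groups of two it is 1/3, and no perfect
separation can push p below ~0.33).

## Age prediction and maturity

A slice (contiguous sub-segment of an original, non-interpolated
trajectory) is locally aligned to each reference; the matched reference
samples are pooled across references with equal weight per matched
(reference, sample) pair — counted once even if a path revisits it — and
the predicted age of a slice sample is the unweighted mean of the pooled
ages. Exact sample times are the target of this analysis, which is why it
uses non-interpolated data. References that admit no path for a given
slice are skipped with a warning. The benchmark samples subjects with
replacement across iterations (subject uniform, then slice start uniform
over valid positions) and scores Pearson r and MSE per prefix length.

Relative maturity is predicted minus chronological age, so a community
resembling a younger child scores negative. The per-phase analysis keeps
only the latest sample per subject and phase before group comparisons, and
the healthy control is leave-one-out: each healthy subject is predicted
from all the others.

Two behaviors of this estimator are worth knowing. First, when per-sample
noise is low, single samples already pin the community state, so
lengthening the slice improves the correlation only marginally while the
joint path — optimized over all slice samples — can shift the first
sample's matched position toward the slice's interior, adding a
forward bias; in the synthetic benchmark this makes MSE grow slightly
with slice length even as the prediction variance falls and r rises. On
sparse, noisy real data the variance term dominates instead and longer
slices pay off. Second, with multiplicative pace variation the expected
pace ratio between subject and reference exceeds one (E[e^Z] > 1 for
symmetric log-paces), giving an age-proportional upward drift that affects
all slice lengths equally. Neither effect is an implementation artifact —
the optimum is enumeration-certified — they are properties of
alignment-based prediction under these conditions. Relatedly, predictions
near the end of the reference span are biased downward because references
cannot vote for ages beyond their follow-up, which is why even healthy
leave-one-out maturity at the last sample sits below zero; the
delayed-vs-healthy contrast, not the absolute healthy level, is the
meaningful quantity.

## Synthetic cohorts

The generator emulates what the analyses assume about infant-gut
development: a shared maturation curve between an infant-like and an
adult-like endpoint profile, E[x(t)] = (1−m)·p_infant + m·p_adult with
m = logistic((u(t) − midpoint)/scale); subject-specific monotone time
warps u(t) = pace · effective time, with pace log-normal across subjects
(σ = 0.25) and effective time accruing at a reduced rate inside a
developmental-stall window for delayed subjects; Dirichlet observation
noise around the expected composition, whose concentration (default 200)
is the single noise knob and guarantees valid compositions; twin pairs
sharing family-level endpoint profiles and pace up to small individual
noise; and day-0-anchored sampling with jittered ~30-day intervals over a
two-year follow-up — matching the cadence and span typical of published
infant cohorts (roughly 20-25 samples per subject). Defaults: 30
subjects, 50 features, logistic midpoint 365 d and scale 120 d, stall
window (120, 420) d at rate 0.15, sampling jitter ±7 d.

What it does **not** emulate: read-count sampling and sequencing error,
taxon-taxon interactions, abrupt regime shifts (antibiotics, weaning),
feature sparsity patterns of real OTU tables, or irregular dropout.
Passing tests therefore certify that the pipeline recovers the intended
signals when its assumptions hold — monotone shared development with pace
variation — not that effect sizes on real cohorts will match.

## Problem sizes and tolerances

The test battery uses cohorts of 14-30 subjects, 10 generator seeds per
directional claim (requiring ≥ 9/10), 100 prediction iterations per seed,
200 random matrices for the enumeration check, and 999 permutations for
PERMANOVA — sizes at which every run completes in well under a minute to
a few minutes on a single core while keeping Monte-Carlo error small
relative to the asserted margins. `scripts/acceptance.py` uses 5 seeds
for the cohort sweeps and 3 for the prediction benchmark for the same
reason. Compositional row sums are enforced to 1e-8; DP-vs-oracle
agreement to 1e-9; trajectory-matrix symmetry to 1e-10.

## Known limitations

* The diagonal baseline needs shared grid points; subjects with disjoint
  observation windows yield missing values.
* Open-begin-end alignment is implemented for "N"-normalized patterns
  only (by design, see above); no Sakoe-Chiba windowing is provided.
* Equal-age samples within one subject are kept in deterministic
  (sample-id) order rather than merged; interpolation handles them, but
  strictly time-stamped input is preferable.
* Age prediction cannot extrapolate beyond the reference pool's age range
  (edge bias discussed above).
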