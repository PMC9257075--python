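# trajalign

Temporal alignment of longitudinal microbiome trajectories.

## The problem

Longitudinal microbiome studies — above all infant-gut cohorts, where the
community matures from an infant-like toward an adult-like composition over
the first years of life — collect a time series of compositional samples
per subject. Subjects share the broad developmental program but differ in
its *pace*: the same succession of community states may run faster in one
infant than another, so comparing samples taken at the same calendar age
("chronologically parallel" samples) understates how similar two
trajectories really are, and can mask clinically relevant signals such as
developmental delay under malnutrition.

`trajalign` addresses this with dynamic time warping (DTW). Given two
trajectories X = (x₁…x_n) and Y = (y₁…y_m) and a pairwise dissimilarity
d(x_i, y_j) ≥ 0 (Bray-Curtis by default), DTW finds a warping path
φ = ((φ_{x,k}, φ_{y,k}))_{k=1..T}, weakly monotone in both coordinates,
minimizing the accumulated weighted dissimilarity

    D_φ(X, Y) = Σ_k w_k · d(x_{φx,k}, y_{φy,k}),

where the admissible transitions and weights w_k come from a configurable
*step pattern* (symmetric2 by default: transitions (i+1,j), (i,j+1),
(i+1,j+1) with weights 1, 1, 2; also symmetricP05 / symmetricP1 /
symmetricP2 and typeIIIc, plus the asymmetric pattern). Scores are divided
by a pattern-specific normalization factor (n+m for the symmetric family,
the query length n for the asymmetric one) so trajectories of different
lengths are comparable. Two modes are supported: **global** alignment
(path from (1,1) to (n,m)), used as a trajectory-to-trajectory
dissimilarity, and **open-begin-end local** alignment, in which a query
segment must be matched in full while the reference may keep an unaligned
head and tail — the engine behind age prediction.

On top of the engine the package provides:

* Gaussian-kernel interpolation of irregularly sampled trajectories onto a
  shared 30-day grid (weights w_i = exp(−(t−t_i)²/window²));
* rare-feature filtering (> 0.1 % relative abundance in ≥ 2 samples),
  trajectory assembly from TSV/BIOM tables and metadata;
* trajectory dissimilarity matrices under the alignment score and two
  naive baselines (chronologically parallel "diagonal" mean; minimum
  pairwise dissimilarity);
* cohort experiments (temporal-shuffle control, early/late half
  comparisons, odd/even same-subject splits with twin cohorts) with
  Mann-Whitney tests, and PERMANOVA for phenotype partitions;
* alignment-based age prediction: a trajectory *slice* is locally aligned
  to every reference trajectory and each sample's age is predicted as the
  mean age of the reference samples it matched; *relative microbiota
  maturity* = predicted − chronological age (negative = delayed);
* a synthetic-cohort generator (shared logistic maturation curve,
  per-subject log-normal pace, Dirichlet compositional noise, twin
  structure, developmental stalls) with ground-truth tables, so the whole
  pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from trajalign import (CohortConfig, generate_cohort, interpolate_cohort,
                       trajectory_dissimilarity, shuffle_experiment, mann_whitney)

trajs, meta, truth = generate_cohort(CohortConfig(n_subjects=6, seed=0))
interp = interpolate_cohort(trajs)          # 30-day grid, window 30
a, b = interp[0], interp[1]
for method in ("aligned", "diagonal", "min"):
    print(method, round(trajectory_dissimilarity(a, b, method), 4))

g = shuffle_experiment(interp, seed=1)      # scores before/after shuffling
u, p = mann_whitney(g["original"], g["shuffled"], alternative="less")
print("medians", round(float(np.median(g["original"])), 4),
      round(float(np.median(g["shuffled"])), 4), "p", round(p, 4))
```

prints

```
aligned 0.3542
diagonal 0.3837
min 0.2847
medians 0.3549 0.3827 p 0.0232
```

The aligned score (0.3542) is lower than the naive diagonal score
(0.3837): warping absorbs the pace difference between the two subjects.
The `min` baseline is lower still, but it ignores temporal structure
entirely — a single pair of similar samples suffices. The shuffle control
shows the alignment score carries temporal signal: destroying the sample
order significantly worsens (raises) the pairwise scores even in this
6-subject cohort (one-sided Mann-Whitney p ≈ 0.02).

A command-line interface mirrors the library
(`trajalign simulate | interpolate | align | pairwise | cohort |
age-predict | maturity`); every run writes a `manifest.json` with its
parameters and seed.

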