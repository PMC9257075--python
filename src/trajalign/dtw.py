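"""Dynamic-time-warping engine: step patterns, global and open-begin-end
alignment, and a brute-force enumeration oracle.

Given two trajectories X = (x_1..x_n) and Y = (y_1..y_m) and a pairwise
dissimilarity d(x_i, y_j) >= 0, DTW searches for a warping path
phi = ((phi_x_1, phi_y_1), ..., (phi_x_T, phi_y_T)) — weakly monotone in
both coordinates — minimizing the accumulated weighted dissimilarity
D_phi = sum_k w_k * d(x_{phi_x_k}, y_{phi_y_k}). The admissible transitions
between consecutive path elements and the weights w_k are given by a *step
pattern*; accumulated costs are divided by a pattern-specific normalization
factor (n + m for the symmetric patterns, the first-series length n for the
asymmetric ones) so scores are comparable across trajectory lengths.

Two modes are supported:

* **global** — the path must start at (1, 1) and end at (n, m);
* **open-begin-end** — the *query* (first axis of the matrix) must be
  matched in full while the reference (second axis) may have an unaligned
  head and tail. This mode requires per-query-sample ("N") normalization so
  that scores ending at different reference columns are comparable.

The DP is the standard quadratic-time recurrence; the enumeration oracle
exhaustively walks every admissible path on small matrices and exists to
certify the DP in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.spatial.distance import cdist

from .io import Trajectory, ValidationError


class AlignmentError(ValueError):
    """Raised when no admissible warping path exists or inputs are invalid."""


class Production(NamedTuple):
    """One admissible DP transition.

    Entering cell (i, j) from the predecessor (i - di, j - dj), the cells
    listed in ``charges`` — offsets (oi, oj) back from (i, j), ordered from
    the predecessor side toward (i, j) — are charged with the given weights.
    """

    di: int
    dj: int
    charges: tuple  # of (oi, oj, weight)


@dataclass(frozen=True)
class StepPattern:
    """Named table of admissible transitions with weights and a
    normalization rule ("N+M", "N", "M" or "none").

    Productions are stored in backtracking priority order: the diagonal
    first, then transitions advancing the first (reference) axis.
    """

    name: str
    productions: tuple
    normalization: str

    def __post_init__(self) -> None:
        for prod in self.productions:
            if (prod.di, prod.dj) == (0, 0):
                raise ValidationError(f"{self.name}: zero-displacement production")
            for oi, oj, w in prod.charges:
                if w <= 0 or oi < 0 or oj < 0 or oi > prod.di or oj > prod.dj:
                    raise ValidationError(f"{self.name}: invalid charge {(oi, oj, w)}")
        if self.normalization not in ("N+M", "N", "M", "none"):
            raise ValidationError(f"{self.name}: unknown normalization")

    def factor(self, n: int, m: int) -> float | None:
        if self.normalization == "N+M":
            return float(n + m)
        if self.normalization == "N":
            return float(n)
        if self.normalization == "M":
            return float(m)
        return None


def _p(di, dj, *charges) -> Production:
    return Production(di, dj, tuple(charges))


#: registry of step patterns; the symmetricP family follows the slope-
#: constrained symmetric forms of Sakoe & Chiba (P = 1/2, 1, 2), typeIIIc
#: the Myers et al. type III local constraint; symmetric2 and asymmetric
#: are the classic unconstrained forms.
STEP_PATTERNS: dict[str, StepPattern] = {}


def _register(pattern: StepPattern) -> StepPattern:
    STEP_PATTERNS[pattern.name] = pattern
    return pattern


symmetric2 = _register(
    StepPattern(
        "symmetric2",
        (
            _p(1, 1, (0, 0, 2.0)),
            _p(1, 0, (0, 0, 1.0)),
            _p(0, 1, (0, 0, 1.0)),
        ),
        "N+M",
    )
)

asymmetric = _register(
    StepPattern(
        "asymmetric",
        (
            _p(1, 1, (0, 0, 1.0)),
            _p(1, 0, (0, 0, 1.0)),
            _p(1, 2, (0, 0, 1.0)),
        ),
        "N",
    )
)

symmetricP05 = _register(
    StepPattern(
        "symmetricP05",
        (
            _p(1, 1, (0, 0, 2.0)),
            _p(2, 1, (1, 0, 2.0), (0, 0, 1.0)),
            _p(1, 2, (0, 1, 2.0), (0, 0, 1.0)),
            _p(3, 1, (2, 0, 2.0), (1, 0, 1.0), (0, 0, 1.0)),
            _p(1, 3, (0, 2, 2.0), (0, 1, 1.0), (0, 0, 1.0)),
        ),
        "N+M",
    )
)

symmetricP1 = _register(
    StepPattern(
        "symmetricP1",
        (
            _p(1, 1, (0, 0, 2.0)),
            _p(2, 1, (1, 0, 2.0), (0, 0, 1.0)),
            _p(1, 2, (0, 1, 2.0), (0, 0, 1.0)),
        ),
        "N+M",
    )
)

symmetricP2 = _register(
    StepPattern(
        "symmetricP2",
        (
            _p(1, 1, (0, 0, 2.0)),
            _p(3, 2, (2, 1, 2.0), (1, 0, 2.0), (0, 0, 1.0)),
            _p(2, 3, (1, 2, 2.0), (0, 1, 2.0), (0, 0, 1.0)),
        ),
        "N+M",
    )
)

typeIIIc = _register(
    StepPattern(
        "typeIIIc",
        (
            _p(1, 1, (0, 0, 1.0)),
            _p(2, 1, (1, 0, 1.0), (0, 0, 1.0)),
            _p(1, 2, (0, 0, 1.0)),
        ),
        "N",
    )
)

#: the slope-constrained family is sometimes referred to with a P01 suffix
#: for the P = 1 member; accept that spelling as an alias.
_ALIASES = {"symmetricP01": "symmetricP1"}


def get_step_pattern(name: str) -> StepPattern:
    """Look up a registered step pattern by name."""
    key = _ALIASES.get(name, name)
    if key not in STEP_PATTERNS:
        raise AlignmentError(
            f"unknown step pattern {name!r}; registered: "
            f"{sorted(STEP_PATTERNS)} (alias {sorted(_ALIASES)})"
        )
    return STEP_PATTERNS[key]


# ---------------------------------------------------------------------------
# Pairwise dissimilarity matrices
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Pairwise sample dissimilarities between two trajectories.

    Rows index the first trajectory passed to :func:`cross_dissimilarity`,
    columns the second. In open-begin-end alignment the rows play the query
    role and the columns the reference role.
    """

    values: np.ndarray
    reference_id: str = ""
    query_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValidationError("dissimilarity matrix must be 2-D and nonempty")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValidationError("dissimilarities must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_METRICS = {"bray-curtis": "braycurtis", "euclidean": "euclidean"}


def cross_dissimilarity(
    a: Trajectory, b: Trajectory, metric: str | Callable = "bray-curtis"
) -> DissimilarityMatrix:
    """All pairwise sample dissimilarities between two trajectories.

    ``metric`` is pluggable: a registered name ("bray-curtis", "euclidean")
    or any callable of two 1-D compositions.
    """
    if a.feature_ids != b.feature_ids:
        raise ValidationError(
            f"feature sets differ between {a.subject_id} and {b.subject_id}"
        )
    if callable(metric):
        vals = cdist(a.samples, b.samples, metric=lambda x, y: float(metric(x, y)))
    else:
        if metric not in _METRICS:
            raise ValidationError(f"unknown metric {metric!r}; known: {sorted(_METRICS)}")
        vals = cdist(a.samples, b.samples, metric=_METRICS[metric])
    return DissimilarityMatrix(vals, reference_id=a.subject_id, query_id=b.subject_id)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A warping path with its accumulated and normalized dissimilarity.

    ``path`` is the ordered list of 1-based matched index pairs; both index
    sequences are weakly monotonically increasing. In global mode the path
    runs from (1, 1) to (n, m); in open-begin-end mode the first axis (the
    query) is covered in full and ``matched_reference_window`` records the
    first and last matched reference index.
    """

    path: list
    accumulated: float
    normalized: float | None
    mode: str
    step_pattern: str
    matched_reference_window: tuple | None = None


def _dp(d: np.ndarray, pattern: StepPattern, free_begin: bool):
    """Fill the accumulated-cost table; returns (D, choice).

    ``choice[i, j]`` is the index of the production used to enter (i, j),
    or -1 for a start cell. Start cells are (0, 0), plus the whole first
    row when ``free_begin`` (each initialized to its own d, i.e. a virtual
    origin step of weight 1). Productions are scanned in priority order
    with strict improvement, so ties resolve to the diagonal first.
    """
    n, m = d.shape
    D = np.full((n, m), np.inf)
    choice = np.full((n, m), -2, dtype=np.int64)
    D[0, 0] = d[0, 0]
    choice[0, 0] = -1
    if free_begin:
        D[0, :] = d[0, :]
        choice[0, :] = -1
    prods = pattern.productions
    for i in range(n):
        Di = D[i]
        for j in range(m):
            best = Di[j]
            best_p = choice[i, j]
            for p_idx, prod in enumerate(prods):
                pi = i - prod.di
                pj = j - prod.dj
                if pi < 0 or pj < 0:
                    continue
                base = D[pi, pj]
                if base == np.inf:
                    continue
                cost = base
                for oi, oj, w in prod.charges:
                    cost += w * d[i - oi, j - oj]
                if cost < best:
                    best = cost
                    best_p = p_idx
            Di[j] = best
            choice[i, j] = best_p
    return D, choice


def _backtrack(choice: np.ndarray, pattern: StepPattern, end: tuple) -> list:
    """Recover the charged-cell path (0-based) ending at ``end``."""
    i, j = end
    path: list = []
    while True:
        p_idx = choice[i, j]
        if p_idx == -1:
            path.append((i, j))
            break
        if p_idx == -2:  # pragma: no cover - guarded by callers
            raise AlignmentError("backtracking reached an unreachable cell")
        prod = pattern.productions[p_idx]
        for oi, oj, _w in reversed(prod.charges):
            path.append((i - oi, j - oj))
        i -= prod.di
        j -= prod.dj
    path.reverse()
    return path


def global_align(d: DissimilarityMatrix, pattern: StepPattern = symmetric2) -> Alignment:
    """Minimal-cost admissible path from (1, 1) to (n, m).

    D(1, 1) is initialized to d(1, 1) with weight 1 (a virtual origin
    step), which makes self-alignment exactly zero. Backtracking ties are
    broken deterministically: diagonal first, then the production advancing
    the reference axis.

    Raises :class:`AlignmentError` when (n, m) is unreachable under a
    slope-constrained pattern.
    """
    vals = d.values
    n, m = vals.shape
    D, choice = _dp(vals, pattern, free_begin=False)
    acc = D[n - 1, m - 1]
    if acc == np.inf:
        raise AlignmentError(
            f"no admissible warping path for shape {n}x{m} under {pattern.name}"
        )
    factor = pattern.factor(n, m)
    path0 = _backtrack(choice, pattern, (n - 1, m - 1))
    return Alignment(
        path=[(i + 1, j + 1) for i, j in path0],
        accumulated=float(acc),
        normalized=None if factor is None else float(acc) / factor,
        mode="global",
        step_pattern=pattern.name,
    )


def local_align(d: DissimilarityMatrix, pattern: StepPattern = asymmetric) -> Alignment:
    """Open-begin-end alignment of the query (rows) inside the reference
    (columns).

    The start is free along the first query row (D(1, j) = d(1, j) for all
    j) and the path may end at any reference column of the last query row;
    the minimizing end column (smallest on ties) is chosen. Requires a
    pattern with per-query-sample ("N") normalization, without which scores
    with different unaligned reference heads are not comparable.
    """
    if pattern.normalization != "N":
        raise AlignmentError(
            "open-begin-end alignment requires an 'N'-normalized pattern "
            f"(per query sample); {pattern.name} normalizes by "
            f"{pattern.normalization!r}"
        )
    vals = d.values
    n, m = vals.shape
    D, choice = _dp(vals, pattern, free_begin=True)
    last = D[n - 1]
    if not np.isfinite(last).any():
        raise AlignmentError(
            f"no admissible open-begin-end path for shape {n}x{m} under {pattern.name}"
        )
    end_j = int(np.argmin(last))  # argmin takes the smallest index on ties
    acc = last[end_j]
    path0 = _backtrack(choice, pattern, (n - 1, end_j))
    cols = [j for _i, j in path0]
    return Alignment(
        path=[(i + 1, j + 1) for i, j in path0],
        accumulated=float(acc),
        normalized=float(acc) / n,
        mode="open-begin-end",
        step_pattern=pattern.name,
        matched_reference_window=(min(cols) + 1, max(cols) + 1),
    )


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX = 7


def enumerate_paths_oracle(
    d: DissimilarityMatrix, pattern: StepPattern, mode: str = "global"
):
    """Exhaustively enumerate admissible warping paths on a small matrix.

    Returns ``(best_cost, best_path)`` with the path 1-based, or
    ``(inf, None)`` when no admissible path exists. Intended as an
    independent test oracle; guarded to n, m <= 7.
    """
    vals = d.values
    n, m = vals.shape
    if n > _ORACLE_MAX or m > _ORACLE_MAX:
        raise ValidationError(f"oracle guard: matrix sides must be <= {_ORACLE_MAX}")
    if mode not in ("global", "open-begin-end"):
        raise ValidationError(f"unknown mode {mode!r}")
    prods = pattern.productions
    best_cost = np.inf
    best_path = None

    def dfs(i: int, j: int, cost: float, path: list) -> None:
        nonlocal best_cost, best_path
        if cost > best_cost:
            return
        at_end = (i == n - 1 and j == m - 1) if mode == "global" else (i == n - 1)
        if at_end and cost < best_cost:
            best_cost = cost
            best_path = list(path)
        for prod in prods:
            ni, nj = i + prod.di, j + prod.dj
            if ni >= n or nj >= m:
                continue
            add = 0.0
            cells = []
            for oi, oj, w in prod.charges:
                cells.append((ni - oi, nj - oj))
                add += w * vals[ni - oi, nj - oj]
            dfs(ni, nj, cost + add, path + cells)

    starts = [(0, 0)] if mode == "global" else [(0, j) for j in range(m)]
    for si, sj in starts:
        dfs(si, sj, float(vals[si, sj]), [(si, sj)])
    if best_path is None:
        return np.inf, None
    return float(best_cost), [(i + 1, j + 1) for i, j in best_path]
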