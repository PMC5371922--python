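"""Cycle similarity by dynamic time warping and representative selection.

Cycles are compared with DTW over a Euclidean local metric (for scalar
samples, the absolute difference).  The DP uses the classic three-neighbor
recursion — each cell adds its local cost to the minimum of the three
adjacent predecessors — optionally restricted to a Sakoe-Chiba band or the
Itakura parallelogram.  The reported distance is the accumulated cost
divided by the warping-path length, so one absolute threshold is
comparable across cycles; before DTW, cycles are peak-normalized and
resampled to a common length (default 256 samples) for the same reason.

Representative selection is a greedy set cover: the remaining cycle with
the minimal summed DTW distance to the other remaining cycles (the
"pattern cycle", a DTW medoid) is picked, every cycle within the coverage
threshold (default 0.005) is assigned to it, and the process repeats on
the uncovered remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import resample as _fourier_resample

from .errors import ParameterError
from .segmentation import CardiacCycle

DEFAULT_COVERAGE_THRESHOLD = 0.005
DEFAULT_COMMON_LENGTH = 256


@dataclass(frozen=True)
class DtwConstraint:
    """Global path constraint: none, Sakoe-Chiba band, or Itakura parallelogram."""

    kind: str = "sakoe_chiba"
    band_width: int | None = None  # index units; None -> 10% of length

    def __post_init__(self) -> None:
        if self.kind not in ("none", "sakoe_chiba", "itakura"):
            raise ParameterError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "sakoe_chiba" and self.band_width is not None and self.band_width < 1:
            raise ParameterError("band_width must be >= 1")

    def window(self, m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-row [lo, hi) column bounds of the admissible region."""
        if self.kind == "none":
            return np.zeros(m, dtype=np.int64), np.full(m, n, dtype=np.int64)
        if self.kind == "sakoe_chiba":
            w = self.band_width if self.band_width is not None else max(1, round(0.1 * max(m, n)))
            if w < abs(m - n):
                raise ParameterError(
                    f"Sakoe-Chiba band {w} infeasible for lengths {m} and {n}"
                )
            i = np.arange(m)
            return np.maximum(0, i - w), np.minimum(n, i + w + 1)
        # Itakura parallelogram: path slope constrained to [1/2, 2]
        if m == 1 or n == 1:
            if m == 1 and n == 1:
                return np.zeros(1, dtype=np.int64), np.ones(1, dtype=np.int64)
            raise ParameterError("Itakura constraint infeasible for length-1 series")
        if (n - 1) > 2 * (m - 1) or (m - 1) > 2 * (n - 1):
            raise ParameterError(
                f"Itakura constraint infeasible for lengths {m} and {n}"
            )
        i = np.arange(m)
        lo = np.maximum(np.ceil(i / 2), (n - 1) - 2 * (m - 1 - i)).astype(np.int64)
        hi = (np.minimum(2 * i, (n - 1) - np.ceil((m - 1 - i) / 2)) + 1).astype(np.int64)
        lo = np.clip(lo, 0, n)
        hi = np.clip(hi, 0, n)
        if np.any(hi <= lo):
            raise ParameterError("Itakura constraint leaves an empty row")
        return lo, hi


@dataclass(frozen=True)
class DtwResult:
    distance: float  # accumulated cost / path length
    accumulated_cost: float
    path: list[tuple[int, int]]


@dataclass(frozen=True)
class CycleSelection:
    representative_indices: list[int]
    assignment: dict[int, int]
    distances: dict[int, float]
    coverage_threshold: float
    max_assigned_distance: float


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance sqrt(sum (x_i - y_i)^2) between equal-length series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


@njit(cache=False)
def _dtw_fill(a, b, lo, hi):  # pragma: no cover - exercised via dtw_distance
    m = a.shape[0]
    n = b.shape[0]
    acc = np.full((m, n), np.inf)
    for i in range(m):
        for j in range(lo[i], hi[i]):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = np.inf
                if i > 0 and acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                    best = acc[i - 1, j - 1]
                if j > 0 and acc[i, j - 1] < best:
                    best = acc[i, j - 1]
            acc[i, j] = c + best
    return acc


def _backtrack(acc: np.ndarray) -> list[tuple[int, int]]:
    m, n = acc.shape
    path = [(m - 1, n - 1)]
    i, j = m - 1, n - 1
    while (i, j) != (0, 0):
        # deterministic tie-break: diagonal, then up, then left
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        path.append((i, j))
    path.reverse()
    return path


def dtw_distance(
    a: np.ndarray, b: np.ndarray, constraint: DtwConstraint = DtwConstraint()
) -> DtwResult:
    """Optimal DTW alignment of two series under the given constraint."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ParameterError("DTW inputs must be non-empty")
    lo, hi = constraint.window(a.size, b.size)
    acc = _dtw_fill(a, b, lo, hi)
    total = float(acc[-1, -1])
    if not np.isfinite(total):
        raise ParameterError("constraint window admits no path")
    path = _backtrack(acc)
    return DtwResult(distance=total / len(path), accumulated_cost=total, path=path)


def _pairwise_dtw_matrix(
    series: list[np.ndarray], constraint: DtwConstraint
) -> np.ndarray:
    k = len(series)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            lo, hi = constraint.window(series[i].size, series[j].size)
            acc = _dtw_fill(series[i], series[j], lo, hi)
            total = float(acc[-1, -1])
            if not np.isfinite(total):
                raise ParameterError("constraint window admits no path")
            # path length via backtrack kept out of the hot loop: use the
            # exact normalization by recovering the optimal path length
            d[i, j] = d[j, i] = total / len(_backtrack(acc))
    return d


def prepare_cycle(cycle: CardiacCycle | np.ndarray, length: int = DEFAULT_COMMON_LENGTH) -> np.ndarray:
    """Peak-normalize and Fourier-resample a cycle to the common DTW length."""
    x = cycle.samples if isinstance(cycle, CardiacCycle) else np.asarray(cycle, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("empty cycle")
    y = _fourier_resample(x, length) if x.size != length else x.astype(np.float64)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def select_representatives(
    cycles: list[CardiacCycle],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    constraint: DtwConstraint = DtwConstraint(),
    common_length: int = DEFAULT_COMMON_LENGTH,
) -> CycleSelection:
    """Greedy reduction of a recording to its fewest representative cycles.

    Every cycle is assigned to a representative at DTW distance strictly
    below ``threshold`` (representatives are assigned to themselves at
    distance 0).  Ties are broken toward the lower cycle index.
    """
    if len(cycles) == 0:
        raise ParameterError("need at least one cycle")
    prepared = [prepare_cycle(c, common_length) for c in cycles]
    dist = _pairwise_dtw_matrix(prepared, constraint)
    n = len(cycles)
    uncovered = list(range(n))
    representatives: list[int] = []
    assignment: dict[int, int] = {}
    distances: dict[int, float] = {}
    while uncovered:
        sums = dist[np.ix_(uncovered, uncovered)].sum(axis=1)
        medoid = uncovered[int(np.argmin(sums))]  # argmin keeps lowest index on ties
        representatives.append(medoid)
        still = []
        for i in uncovered:
            d = float(dist[medoid, i])
            if i == medoid or d < threshold:
                assignment[i] = medoid
                distances[i] = 0.0 if i == medoid else d
            else:
                still.append(i)
        uncovered = still
    max_assigned = max(distances.values()) if distances else 0.0
    assert set(assignment) == set(range(n)), "every cycle must be assigned"
    return CycleSelection(
        representative_indices=sorted(representatives),
        assignment=assignment,
        distances=distances,
        coverage_threshold=threshold,
        max_assigned_distance=max_assigned,
    )
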