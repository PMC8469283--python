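"""Maximal information coefficient (MIC) between neural response and EMG.

For a paired sample D = {(r_i, m_i)} of n points, the MIC is

    MIC(D) = max_{r*m < B(n)} M(D)_{r,m},
    M(D)_{r,m} = I*(D, r, m) / log2 min(r, m),
    I*(D, r, m) = max over all r-by-m grids G of I(D|G),

where I(D|G) is the plug-in mutual information (bits) of the contingency
table induced by the grid, and B(n) = n^alpha caps the grid resolution.
MIC lies in [0, 1], is symmetric in its two variables, equals 1 for a
noiseless functional relationship and 0 for independence.

Grid search comes in two modes.  ``exhaustive`` enumerates every placement
of cut points between adjacent distinct data values (only feasible for tiny
n; it is the reference the fast path is validated against).  ``heuristic``
fixes one axis — enumerating its cut placements when few enough, otherwise
using a mass equipartition — and optimises the other axis exactly by dynamic
programming over clump boundaries (MINE-style), in both orientations.  The
heuristic can never exceed the exhaustive value because it maximises over a
subset of the same grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log2

import numpy as np
from scipy.special import xlogy


class DataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# paired sample
# ---------------------------------------------------------------------------

@dataclass
class PairedSample:
    """Paired neural-response / muscle-activity values."""

    r: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).ravel()
        self.m = np.asarray(self.m, dtype=float).ravel()
        if self.r.size != self.m.size:
            raise DataError("r and m must have equal length")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.m))):
            raise DataError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.r.size)

    def swapped(self) -> "PairedSample":
        return PairedSample(r=self.m.copy(), m=self.r.copy())


# ---------------------------------------------------------------------------
# plug-in mutual information
# ---------------------------------------------------------------------------

def _mi_bits_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a contingency table, 0*log0 = 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    # I = [sum c log c - sum row log row - sum col log col + n log n] / (n ln 2)
    s_cells = xlogy(counts, counts).sum()
    s_rows = xlogy(counts.sum(axis=1), counts.sum(axis=1)).sum()
    s_cols = xlogy(counts.sum(axis=0), counts.sum(axis=0)).sum()
    val = (s_cells - s_rows - s_cols + n * np.log(n)) / (n * np.log(2))
    return max(0.0, float(val))


def grid_mutual_information(sample: PairedSample, row_edges: np.ndarray,
                            col_edges: np.ndarray) -> float:
    """I(D|G) in bits for the grid given by full (outer included) edges."""
    row_edges = np.asarray(row_edges, dtype=float)
    col_edges = np.asarray(col_edges, dtype=float)
    for edges in (row_edges, col_edges):
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")
    if (sample.r.min() < row_edges[0] or sample.r.max() > row_edges[-1]
            or sample.m.min() < col_edges[0]
            or sample.m.max() > col_edges[-1]):
        raise ValueError("every point must fall inside the grid")
    counts, _, _ = np.histogram2d(sample.r, sample.m,
                                  bins=[row_edges, col_edges])
    return _mi_bits_from_counts(counts)


# ---------------------------------------------------------------------------
# grid search machinery
# ---------------------------------------------------------------------------

def _compress(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Map values to dense ranks of their distinct sorted values."""
    distinct, inverse = np.unique(values, return_inverse=True)
    return inverse, distinct.size


def _joint_table(sample: PairedSample) -> np.ndarray:
    """Distinct-value joint count table (d_r x d_m)."""
    ir, dr = _compress(sample.r)
    im, dm = _compress(sample.m)
    table = np.zeros((dr, dm))
    np.add.at(table, (ir, im), 1.0)
    return table


def _partition_counts(table: np.ndarray, cuts: tuple[int, ...],
                      axis: int) -> np.ndarray:
    """Merge distinct-value bins into parts at the given cut positions.

    ``cuts`` are positions in 1..d-1: a cut at position c separates distinct
    values c-1 and c (geometrically midway between them).
    """
    bounds = np.concatenate([[0], np.asarray(cuts, dtype=int)])
    return np.add.reduceat(table, bounds, axis=axis)


def max_grid_mi(sample: PairedSample, r: int, m: int,
                mode: str = "heuristic", c: float = 15.0,
                enum_limit: int = 1000) -> float:
    """I*(D, r, m): maximal grid mutual information in bits.

    ``exhaustive`` enumerates all cut placements on both axes (use only for
    tiny n).  ``heuristic`` is the MINE-style search described in the module
    docstring; it never exceeds the exhaustive value and matches it whenever
    the fixed-axis placements can be fully enumerated (``enum_limit``).
    """
    if r < 2 or m < 2:
        raise ValueError("grid must be at least 2 x 2")
    table = _joint_table(sample)
    dr, dm = table.shape
    if dr < 2 or dm < 2:
        return 0.0  # a constant marginal carries no information
    if mode == "exhaustive":
        return _exhaustive_max_mi(table, r, m)
    if mode == "heuristic":
        a = _orientation_profile(table, r_max=r, n_fixed=m, c=c,
                                 enum_limit=enum_limit)[r - 1]
        b = _orientation_profile(table.T, r_max=m, n_fixed=r, c=c,
                                 enum_limit=enum_limit)[m - 1]
        return float(max(a, b))
    raise ValueError(f"unknown mode {mode!r}")


def _exhaustive_max_mi(table: np.ndarray, r: int, m: int) -> float:
    dr, dm = table.shape
    best = 0.0
    r_eff = min(r, dr)
    m_eff = min(m, dm)
    for row_cuts in combinations(range(1, dr), r_eff - 1):
        rows = _partition_counts(table, row_cuts, axis=0)
        for col_cuts in combinations(range(1, dm), m_eff - 1):
            cells = _partition_counts(rows, col_cuts, axis=1)
            best = max(best, _mi_bits_from_counts(cells))
    return best


def _equipartition_cuts(marginal: np.ndarray, parts: int) -> tuple[int, ...]:
    """Cut positions splitting a distinct-value marginal into ~equal masses."""
    d = marginal.size
    if parts >= d:
        return tuple(range(1, d))
    cum = np.cumsum(marginal)
    total = cum[-1]
    targets = total * np.arange(1, parts) / parts
    cuts = np.searchsorted(cum, targets, side="left") + 1
    cuts = np.unique(np.clip(cuts, 1, d - 1))
    return tuple(int(c) for c in cuts)


def _fixed_axis_placements(table: np.ndarray, n_fixed: int,
                           enum_limit: int) -> list[tuple[int, ...]]:
    """Candidate cut placements for the fixed (column) axis.

    For small samples (n <= 32) every C(d-1, n_fixed-1) placement is
    enumerated as long as that count stays below ``enum_limit`` — together
    with the exact row DP this makes the heuristic search exhaustive there.
    Larger samples use the mass equipartition of the fixed marginal.
    """
    d_fixed = table.shape[1]
    k = min(d_fixed - 1, n_fixed - 1)
    if int(table.sum()) <= 32 and comb(d_fixed - 1, k) <= enum_limit:
        return list(combinations(range(1, d_fixed), k))
    return [_equipartition_cuts(table.sum(axis=0), n_fixed)]


def _dp_profile_rows(cols: np.ndarray, r_max: int, c: float) -> np.ndarray:
    """Exact DP over row partitions of a (clumps x fixed-cols) count table.

    With the column partition fixed, the mutual information decomposes as
    I = [S - sum_col n_c ln n_c + n ln n] / (n ln 2) with
    S = sum over row-parts of (sum_j n_pj ln n_pj - n_p ln n_p), which is
    additive over parts, so the optimal S is found by dynamic programming
    over clump prefix boundaries.  One DP sweep yields the whole profile:
    the returned array holds the best I (bits) over partitions into at most
    l rows for every l = 1..r_max.  Merging adjacent clumps can only lose
    information, so the clump count is capped at ``c * r_max`` (mass
    equipartition of the row marginal) to stay tractable at large n.
    """
    d = cols.shape[0]
    cap = max(2 * r_max, int(round(c * r_max)))
    if d > cap:
        cuts = _equipartition_cuts(cols.sum(axis=1), cap)
        clumps = _partition_counts(cols, cuts, axis=0)
    else:
        clumps = cols
    k = clumps.shape[0]

    # prefix cumulative counts: cum[i] = clumps[:i].sum(axis=0)
    cum = np.vstack([np.zeros(clumps.shape[1]), np.cumsum(clumps, axis=0)])
    # part score s[j, i] for the part spanning clumps j..i-1 (j <= i):
    #   sum_col n ln n - n_tot ln n_tot   (empty part scores 0)
    seg = cum[np.newaxis, :, :] - cum[:, np.newaxis, :]  # (k+1, k+1, cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_term = xlogy(seg, seg).sum(axis=2)
        tot = seg.sum(axis=2)
        s = cell_term - xlogy(tot, tot)
    valid = np.triu(np.ones(s.shape, dtype=bool))
    s = np.where(valid, s, -np.inf)

    n = float(cum[-1].sum())
    fixed_term = n * np.log(n) - xlogy(cum[-1], cum[-1]).sum()

    best_s = np.empty(r_max)
    dp = s[0, :]  # l = 1: a single part spanning clumps 0..i-1
    best_s[0] = dp[-1]
    for l in range(1, min(r_max, k)):
        # dp_new[i] = max_j dp[j] + s[j, i]
        dp = np.max(dp[:, np.newaxis] + s, axis=0)
        best_s[l] = dp[-1]
    best_s[min(r_max, k):] = best_s[min(r_max, k) - 1]  # no finer than clumps
    return np.maximum(0.0, (best_s + fixed_term) / (n * np.log(2)))


def _orientation_profile(table: np.ndarray, r_max: int, n_fixed: int,
                         c: float, enum_limit: int) -> np.ndarray:
    """Best I (bits) per free-axis part count with the column axis fixed."""
    best = np.zeros(r_max)
    for cuts in _fixed_axis_placements(table, n_fixed, enum_limit):
        cols = _partition_counts(table, tuple(cuts), axis=1)
        np.maximum(best, _dp_profile_rows(cols, r_max, c), out=best)
    return best


# ---------------------------------------------------------------------------
# the MIC statistic
# ---------------------------------------------------------------------------

@dataclass
class MICResult:
    """MIC with its characteristic matrix and the grid that achieved it."""

    mic: float
    best_grid: tuple[int, int]
    B: float
    characteristic_matrix: dict[tuple[int, int], float]
    n: int
    alpha: float
    mode: str


def grid_resolution_bound(n: int, alpha: float = 0.6) -> float:
    """B(n) = n^alpha, floored so a 2x2 grid is always admissible."""
    return max(float(n) ** alpha, 4.0 + 1e-9)


def mic(sample: PairedSample, alpha: float = 0.6, c: float = 15.0,
        mode: str = "heuristic", enum_limit: int = 1000) -> MICResult:
    """Maximal information coefficient of a paired sample.

    Fills the characteristic matrix M(D)_{r,m} = I*(r, m) / log2 min(r, m)
    over all admissible grid shapes (r, m >= 2, r*m < B(n)) and returns its
    maximum.  Symmetric in the two variables by construction.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if sample.n < 4:
        raise DataError("need at least 4 paired observations")
    B = grid_resolution_bound(sample.n, alpha)
    char: dict[tuple[int, int], float] = {}

    if mode == "exhaustive":
        r = 2
        while r * 2 < B:
            m = 2
            while r * m < B:
                i_star = max_grid_mi(sample, r, m, mode=mode)
                char[(r, m)] = i_star / log2(min(r, m))
                m += 1
            r += 1
    elif mode == "heuristic":
        # one DP sweep per (orientation, fixed-axis size) yields the best
        # value for every free-axis size at once
        table = _joint_table(sample)
        for oriented, swap in ((table, False), (table.T, True)):
            if min(oriented.shape) < 1 or max(oriented.shape) < 2:
                continue
            m_fixed = 2
            while 2 * m_fixed < B:
                r_max = int(np.ceil(B / m_fixed)) - 1
                while r_max * m_fixed >= B:
                    r_max -= 1
                if r_max < 2:
                    break
                if oriented.shape[0] < 2 or oriented.shape[1] < 2:
                    profile = np.zeros(r_max)
                else:
                    profile = _orientation_profile(
                        oriented, r_max=r_max, n_fixed=m_fixed, c=c,
                        enum_limit=enum_limit)
                for l in range(2, r_max + 1):
                    shape = (m_fixed, l) if swap else (l, m_fixed)
                    value = profile[l - 1] / log2(min(l, m_fixed))
                    if value > char.get(shape, 0.0):
                        char[shape] = value
                m_fixed += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best, best_grid = 0.0, (2, 2)
    for shape, value in sorted(char.items()):
        if value > best + 1e-12:
            best, best_grid = value, shape
    return MICResult(mic=min(1.0, best), best_grid=best_grid, B=B,
                     characteristic_matrix=char, n=sample.n, alpha=alpha,
                     mode=mode)


def mic_value(x: np.ndarray, y: np.ndarray, **kwargs) -> float:
    """Convenience wrapper: MIC of two value arrays."""
    return mic(PairedSample(r=x, m=y), **kwargs).mic


# ---------------------------------------------------------------------------
# trial bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapMIC:
    values: np.ndarray
    mean: float
    sd: float
    k: int
    reps: int


def bootstrap_mic(trial_samples: list[PairedSample], k: int = 30,
                  reps: int = 100,
                  rng: np.random.Generator | int | None = None,
                  **mic_kwargs) -> BootstrapMIC:
    """Trial (walking-step) bootstrap of the MIC.

    Each replicate draws ``k`` trials with replacement (defaults: 30 trials,
    100 replicates), concatenates them into one paired sample and computes
    its MIC; sampling more trials shrinks the small-sample underestimation
    bias of the statistic.
    """
    if not trial_samples:
        raise DataError("need at least one trial")
    if k < 1 or reps < 1:
        raise ValueError("k and reps must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = np.empty(reps)
    for rep in range(reps):
        chosen = rng.integers(0, len(trial_samples), k)
        r = np.concatenate([trial_samples[i].r for i in chosen])
        m = np.concatenate([trial_samples[i].m for i in chosen])
        values[rep] = mic(PairedSample(r=r, m=m), **mic_kwargs).mic
    return BootstrapMIC(values=values, mean=float(values.mean()),
                        sd=float(values.std(ddof=1)) if reps > 1 else 0.0,
                        k=k, reps=reps)


__all__ = [
    "BootstrapMIC",
    "DataError",
    "MICResult",
    "PairedSample",
    "bootstrap_mic",
    "grid_mutual_information",
    "grid_resolution_bound",
    "max_grid_mi",
    "mic",
    "mic_value",
]
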