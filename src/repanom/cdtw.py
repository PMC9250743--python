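"""Circular Dynamic Time Warping (CDTW) on the phase cylinder.

A single circular template of ``n`` evenly spaced phases (template[i] =
2*pi*i/n) is matched against an unsegmented phase sequence of arbitrary
length ``m``.  Because the template axis is cyclic, the cumulative-cost table
lives on a cylinder: the row predecessor of row 0 is row n-1, so one template
round is reused for every repetition in the signal.  The optimal warping path
yields, per sample, the approximately closest monotonically progressing
(ACMP) phase; deviations of the raw extracted phase from the ACMP phase are
the phase-fluctuation anomaly score, and ACMP wraps past 2*pi delimit
repetition periods.

Path moves are the three standard DTW moves with the row index taken modulo
n: (i, j-1), (i-1 mod n, j-1) and (i-1 mod n, j).  The within-column cyclic
dependency introduced by the vertical move is resolved by sweeping each
column to a fixed point (two sweeps suffice in practice; the loop is capped
at n).  The start is free over all rows of column 0 and the end is the
minimal-cost row of the last column, so the signal may start and end at any
phase value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularTemplate",
    "CdtwTable",
    "WarpingPath",
    "circular_distance",
    "build_table",
    "traceback",
    "phase_anomaly_score",
    "segment_periods",
    "Segment",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CircularTemplate:
    n: int = 50

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("template needs n >= 3 phases")

    @property
    def values(self) -> np.ndarray:
        return TWO_PI * np.arange(self.n) / self.n


def circular_distance(a, b):
    """Wrap-aware distance between phase angles, in [0, pi].

    D(a, b) = min(|a - b| mod 2pi, 2pi - |a - b| mod 2pi); symmetric, zero on
    the diagonal, and insensitive to whole-turn offsets of either argument.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), TWO_PI)
    return np.where(d <= np.pi, d, TWO_PI - d)


@dataclass
class CdtwTable:
    costs: np.ndarray  # (n, m) cumulative costs on the cylinder
    local: np.ndarray  # (n, m) local distances D(template[i], phi_j)
    template: CircularTemplate


def build_table(phases: np.ndarray, template: CircularTemplate) -> CdtwTable:
    """Cumulative-cost table of CDTW (O(m*n)).

    Column 0 holds bare local distances for every row (free start phase).
    Each later column j is first relaxed from column j-1 through the
    horizontal and diagonal moves, then the cyclic vertical move is relaxed
    by repeated in-column sweeps until no entry improves.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    m = phases.size
    if m == 0:
        raise ValueError("empty phase sequence")
    n = template.n
    local = circular_distance(template.values[:, None], phases[None, :])
    costs = np.empty((n, m))
    costs[:, 0] = local[:, 0]
    for j in range(1, m):
        prev = costs[:, j - 1]
        base = np.minimum(prev, np.roll(prev, 1))  # (i, j-1) vs (i-1 mod n, j-1)
        col = local[:, j] + base
        lj = local[:, j]
        for _ in range(n):  # fixed-point relaxation of the cyclic vertical move
            changed = False
            for i in range(n):
                cand = col[i - 1] + lj[i]
                if cand < col[i]:
                    col[i] = cand
                    changed = True
            if not changed:
                break
        costs[:, j] = col
    return CdtwTable(costs, local, template)


@dataclass
class WarpingPath:
    """Optimal cylindrical warping path and the per-sample ACMP assignment."""

    pairs: list[tuple[int, int]]  # (row mod n, column), path order
    rows_unwrapped: np.ndarray  # unwrapped row index per path step
    i_mid: np.ndarray  # (m,) unwrapped middle matched row per column
    run_lo: np.ndarray  # (m,) first unwrapped row matched to each column
    run_hi: np.ndarray  # (m,) last unwrapped row matched to each column
    n: int
    cost: float

    @property
    def acmp(self) -> np.ndarray:
        """ACMP phase per sample: 2*pi*(i_mid mod n)/n, in [0, 2*pi)."""
        return TWO_PI * np.mod(self.i_mid, self.n) / self.n

    @property
    def rounds(self) -> np.ndarray:
        """Template round index per sample (increments at each 2*pi wrap)."""
        return self.i_mid // self.n

    def column_rows(self, j: int) -> np.ndarray:
        """Unwrapped rows matched to column j (consecutive)."""
        return np.arange(self.run_lo[j], self.run_hi[j] + 1)


def traceback(table: CdtwTable) -> WarpingPath:
    """Trace the minimal-cost path back from the last column (free end).

    Ties prefer the predecessor advancing the template index least, i.e.
    (i, j-1) before (i-1, j-1) before (i-1 mod n, j); among equal-cost row
    predecessors the earliest in that fixed order wins, which makes the path
    deterministic.  At most n-1 vertical moves are taken within one column
    (a full-circle match within a single sample is degenerate and never
    optimal because every column has at most one zero local distance).
    """
    costs, local, n = table.costs, table.local, table.template.n
    m = costs.shape[1]
    i = int(np.argmin(costs[:, m - 1]))
    cost = float(costs[i, m - 1])
    rev: list[tuple[int, int]] = [(i, m - 1)]
    j = m - 1
    vertical_run = 0
    while j > 0:
        # candidates as (value, tie-break order, (row, col))
        cands = [
            (costs[i, j - 1], 0, (i, j - 1)),
            (costs[(i - 1) % n, j - 1], 1, ((i - 1) % n, j - 1)),
        ]
        if vertical_run < n - 1:
            cands.append((costs[(i - 1) % n, j], 2, ((i - 1) % n, j)))
        _, move, (pi_, pj_) = min(cands, key=lambda t: (t[0], t[1]))
        vertical_run = vertical_run + 1 if move == 2 else 0
        i, j = pi_, pj_
        rev.append((i, j))
    rev.reverse()

    # unwrap rows: row advance is 0 (horizontal) or +1 (diagonal/vertical)
    rows_unwrapped = np.empty(len(rev), dtype=int)
    rows_unwrapped[0] = rev[0][0]
    for k in range(1, len(rev)):
        advance = (rev[k][0] - rev[k - 1][0]) % n
        rows_unwrapped[k] = rows_unwrapped[k - 1] + advance

    # per-column run of matched rows (consecutive in unwrapped rows, so a
    # wrap-crossing run stays contiguous); i_mid is the lower middle
    run_lo = np.empty(m, dtype=int)
    run_hi = np.empty(m, dtype=int)
    cols = np.array([j for _, j in rev])
    first = np.searchsorted(cols, np.arange(m), side="left")
    last = np.searchsorted(cols, np.arange(m), side="right") - 1
    run_lo[:] = rows_unwrapped[first]
    run_hi[:] = rows_unwrapped[last]
    i_mid = run_lo + (run_hi - run_lo) // 2
    return WarpingPath(rev, rows_unwrapped, i_mid, run_lo, run_hi, n, cost)


def phase_anomaly_score(extracted_angles: np.ndarray, acmp: np.ndarray) -> np.ndarray:
    """Per-sample phase-fluctuation score: circular distance of the raw
    (unsmoothed) extracted phase from the ACMP phase, in [0, pi]."""
    extracted_angles = np.asarray(extracted_angles, dtype=float)
    acmp = np.asarray(acmp, dtype=float)
    if extracted_angles.shape != acmp.shape:
        raise ValueError("extracted and ACMP sequences must have equal length")
    return circular_distance(extracted_angles, acmp)


def brute_force_min_cost(
    phases: np.ndarray, template: CircularTemplate, prune: bool = True
) -> float:
    """Exhaustive minimum cost over all forward-monotone cylindrical paths.

    Independent reference for validating the DP: recursively enumerates every
    path (free start row, free end row, the three moves, at most n rows
    matched per column).  With ``prune`` the search discards branches whose
    partial cost already exceeds the best complete path — an admissible bound
    that preserves exactness.  Exponential; intended for tiny instances only.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    m = phases.size
    n = template.n
    local = circular_distance(template.values[:, None], phases[None, :])
    best = [np.inf]

    def rec(i: int, j: int, vert_run: int, cost: float):
        if prune and cost >= best[0]:
            return
        if j == m - 1:
            # further vertical moves only add cost; this is a complete path
            if cost < best[0]:
                best[0] = cost
            return
        rec(i, j + 1, 0, cost + local[i, j + 1])
        rec((i + 1) % n, j + 1, 0, cost + local[(i + 1) % n, j + 1])
        if vert_run < n - 1:
            rec((i + 1) % n, j, vert_run + 1, cost + local[(i + 1) % n, j])

    for i0 in range(n):
        rec(i0, 0, 0, float(local[i0, 0]))
    return float(best[0])


@dataclass(frozen=True)
class Segment:
    start: int  # inclusive sample index
    end: int  # exclusive
    partial: bool

    def __len__(self):
        return self.end - self.start


def segment_periods(path: WarpingPath) -> list[Segment]:
    """Split [0, m) into periods at ACMP wraps past 2*pi.

    A boundary sits at each sample where the template round increments.  The
    first and last segments are flagged partial (they rarely span a full
    round); interior segments each cover one full repetition.
    """
    rounds = path.rounds
    m = rounds.size
    boundaries = [int(j) for j in np.nonzero(np.diff(rounds) > 0)[0] + 1]
    edges = [0] + boundaries + [m]
    segs = []
    for k in range(len(edges) - 1):
        if edges[k] == edges[k + 1]:
            continue
        partial = k == 0 or k == len(edges) - 2
        segs.append(Segment(edges[k], edges[k + 1], partial))
    return segs
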