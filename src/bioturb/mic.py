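"""Maximal information coefficient (MIC) for ASV-activity association.

The estimator follows the MINE scheme: for every grid size (k, l) with
k*l <= B(n) = n^alpha, one axis is equipartitioned into l bins by rank
quantiles and the other axis's k-partition is optimized by dynamic
programming over clump boundaries (runs of consecutive points that share a
row never need to be cut). Both axis orientations are computed and the
characteristic-matrix entry is the larger normalized mutual information
I*/log2(min(k, l)); MIC is the matrix maximum. The statistic is fully
deterministic: rank ties are grouped and never split, and tie-breaks
follow stable input order.

All entropies are in bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.6
DEFAULT_C = 15.0


@dataclass(frozen=True)
class MicResult:
    mic: float
    x_bins: int
    y_bins: int
    n: int
    alpha: float
    c: float


def grid_bound(n: int, alpha: float = DEFAULT_ALPHA) -> int:
    """Maximal grid size B(n) = floor(n^alpha), never below 4 so the 2x2
    grid always exists."""
    return max(int(np.floor(n ** alpha)), 4)


def _allowed_cuts(sorted_vals: np.ndarray) -> np.ndarray:
    """Positions (in sorted order) where a cut does not split tied values."""
    n = sorted_vals.size
    interior = np.nonzero(sorted_vals[1:] != sorted_vals[:-1])[0] + 1
    return np.concatenate(([0], interior, [n]))


def _equipartition(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each point a bin id, targeting equal occupancy without
    splitting ties: each rank-quantile boundary snaps to the nearest
    admissible cut."""
    n = values.size
    order = np.argsort(values, kind="stable")
    sv = values[order]
    allowed = _allowed_cuts(sv)
    cuts = [0]
    for j in range(1, n_bins):
        target = j * n / n_bins
        cand = allowed[np.argmin(np.abs(allowed - target))]
        if cand > cuts[-1] and cand < n:
            cuts.append(int(cand))
    cuts.append(n)
    assign_sorted = np.empty(n, dtype=np.int64)
    for b in range(len(cuts) - 1):
        assign_sorted[cuts[b]: cuts[b + 1]] = b
    out = np.empty(n, dtype=np.int64)
    out[order] = assign_sorted
    return out


def _clumps(x: np.ndarray, rows: np.ndarray, n_rows: int, k_hat: int):
    """Atom partition of the x axis for the DP.

    Points are sorted by x; x-ties are merged; maximal runs of points in
    the same row form clumps. If there are more clumps than ``k_hat`` they
    are merged into superclumps of near-equal point counts. Returns
    (cum, row_cum): cumulative point counts (m+1,) and cumulative per-row
    counts (m+1, n_rows) over atom boundaries.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    q = rows[order].astype(np.int64)
    if np.any(xs[1:] == xs[:-1]):
        # x-ties spanning several rows become their own pseudo-row so no
        # cut can fall inside them
        q = q.copy()
        start = 0
        pseudo = n_rows
        for i in range(1, n + 1):
            if i == n or xs[i] != xs[start]:
                if i - start > 1 and np.unique(q[start:i]).size > 1:
                    q[start:i] = pseudo
                    pseudo += 1
                start = i
    boundaries = np.nonzero(q[1:] != q[:-1])[0] + 1
    edges = np.concatenate(([0], boundaries, [n]))
    if edges.size - 1 > k_hat:
        # superclumps: equipartition the clump sequence by point count
        clump_sizes = np.diff(edges)
        clump_id_of_point = np.repeat(np.arange(edges.size - 1), clump_sizes)
        merged = _equipartition(clump_id_of_point.astype(float), k_hat)
        boundaries = np.nonzero(merged[1:] != merged[:-1])[0] + 1
        edges = np.concatenate(([0], boundaries, [n]))
    m = edges.size - 1
    true_rows = rows[order]
    one_hot = np.zeros((n, n_rows))
    one_hot[np.arange(n), true_rows] = 1.0
    cum_points = np.vstack([np.zeros(n_rows), np.cumsum(one_hot, axis=0)])
    row_cum = cum_points[edges]
    return edges.astype(np.int64), row_cum


def _plogp(c: np.ndarray) -> np.ndarray:
    out = np.zeros_like(c, dtype=float)
    nz = c > 0
    out[nz] = c[nz] * np.log2(c[nz])
    return out


def _optimize_axis(
    x: np.ndarray, rows: np.ndarray, n_rows: int, kmax: int, c: float
) -> np.ndarray:
    """Best mutual information (bits) using <= k columns on x for
    k = 2..kmax, with the row partition of the other axis fixed.

    Implements the clump/superclump dynamic program: F(t, l) is the best
    value of -H(rows | columns) over partitions of the first t atoms into
    l columns, with probabilities conditioned on those atoms; the recursion
    rescales the prefix term by its point share.
    """
    k_hat = max(int(c * kmax), kmax)
    cum_edges, row_cum = _clumps(x, rows, n_rows, k_hat)
    cum = cum_edges.astype(float)
    m = cum.size - 1
    n = cum[-1]
    total_rows = row_cum[-1].astype(float)
    h_q = np.log2(n) - _plogp(total_rows).sum() / n

    # H(rows | one column spanning atoms (s, t]) for every s < t, built in
    # one shot from cumulative row counts
    counts3 = row_cum[None, :, :] - row_cum[:, None, :]  # (s, t, row)
    npts = cum[None, :] - cum[:, None]  # (s, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        plp = np.where(counts3 > 0, counts3 * np.log2(np.maximum(counts3, 1)), 0.0)
        h_col = np.where(npts > 0, np.log2(np.maximum(npts, 1)) - plp.sum(axis=2) / np.maximum(npts, 1), 0.0)

    valid_t = np.arange(m + 1)
    ratio = np.where(npts > 0, cum[:, None] / np.maximum(cum[None, :], 1e-300), 0.0)
    wlast = np.where(npts > 0, npts / np.maximum(cum[None, :], 1e-300), 0.0)
    s_idx = np.arange(m + 1)[:, None]
    t_idx = np.arange(m + 1)[None, :]

    best = np.full(kmax + 1, -np.inf)
    f_prev = np.full(m + 1, -np.inf)
    f_prev[1:] = -h_col[0, 1:]
    # l = 1 column gives I = 0 by construction; record from l = 2 upward
    for l in range(2, kmax + 1):
        with np.errstate(invalid="ignore"):
            vals = ratio * f_prev[:, None] - wlast * h_col  # (s, t)
        vals = np.where((s_idx >= l - 1) & (s_idx < t_idx), vals, -np.inf)
        np.nan_to_num(vals, copy=False, nan=-np.inf)
        f_new = vals.max(axis=0)
        f_new[:l] = -np.inf
        if m >= l and np.isfinite(f_new[m]):
            best[l] = h_q + f_new[m]
        f_prev = f_new
    # "<= k columns": running maximum
    out = np.full(kmax + 1, 0.0)
    run = 0.0
    for k in range(2, kmax + 1):
        if np.isfinite(best[k]):
            run = max(run, best[k])
        out[k] = run
    return out


def mic_score(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    c: float = DEFAULT_C,
    b_max: int | None = None,
) -> MicResult:
    """MIC of two real vectors.

    ``b_max`` overrides the grid-size budget B(n) (used by tests that pin
    the search space); otherwise B(n) = max(floor(n^alpha), 4). A constant
    vector has no informative partition and scores 0 by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("mic_score: length mismatch")
    n = x.size
    if n < 8:
        raise ValueError("mic_score: need n >= 8")
    if not 0 < alpha <= 1:
        raise ValueError("mic_score: alpha must be in (0, 1]")
    if c < 1:
        raise ValueError("mic_score: c must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("mic_score: constant vector, MIC = 0 by convention")
        return MicResult(0.0, 2, 2, n, alpha, c)
    b = b_max if b_max is not None else grid_bound(n, alpha)

    # orientation 1: rows on y (l bins), columns optimized on x (<= k)
    i_rows_y: dict[int, np.ndarray] = {}
    # orientation 2: rows on x (k bins), columns optimized on y (<= l)
    i_rows_x: dict[int, np.ndarray] = {}
    for l in range(2, b // 2 + 1):
        kmax = b // l
        ry = _equipartition(y, l)
        i_rows_y[l] = _optimize_axis(x, ry, int(ry.max()) + 1, kmax, c)
        rx = _equipartition(x, l)
        i_rows_x[l] = _optimize_axis(y, rx, int(rx.max()) + 1, kmax, c)

    best, best_grid = 0.0, (2, 2)
    for l in range(2, b // 2 + 1):  # y bins
        for k in range(2, b // l + 1):  # x bins
            i1 = i_rows_y[l][k]
            i2 = i_rows_x[k][l] if k in i_rows_x and l < i_rows_x[k].size else 0.0
            val = max(i1, i2) / np.log2(min(k, l))
            val = float(np.clip(val, 0.0, 1.0))
            if val > best + 1e-12:
                best, best_grid = val, (k, l)
    return MicResult(best, best_grid[0], best_grid[1], n, alpha, c)


def mic_matrix(
    abundance: pd.DataFrame,
    activities: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    c: float = DEFAULT_C,
) -> pd.DataFrame:
    """MIC per (ASV, activity) pair.

    ``abundance`` is sample x ASV, ``activities`` sample x activity, with
    identical sample ordering. Deterministic: no randomness in MIC.
    """
    if list(abundance.index) != list(activities.index):
        raise ValueError("mic_matrix: sample mismatch between inputs")
    out = np.zeros((abundance.shape[1], activities.shape[1]))
    act = {a: activities[a].to_numpy() for a in activities.columns}
    for i, asv in enumerate(abundance.columns):
        xv = abundance[asv].to_numpy()
        for j, a in enumerate(activities.columns):
            out[i, j] = mic_score(xv, act[a], alpha=alpha, c=c).mic
    return pd.DataFrame(out, index=abundance.columns, columns=activities.columns)
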