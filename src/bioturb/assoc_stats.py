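"""Screening statistics: Spearman correlation with significance, Bray-Curtis
distances, Mantel test, PERMANOVA, alpha diversity and PCoA.

Permutation tests use the add-one estimator p = (1 + #{perm >= obs}) / (1 + n_perm)
and an explicit seed, so p-values are reproducible and never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal sample-by-sample distance matrix."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distance")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null |rho| distribution over all n! rank permutations (tie-free)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return np.abs(1.0 - 6.0 * d2 / (n * (n * n - 1)))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided significance.

    rho is the Pearson correlation of average-ranked values. p comes from
    the t-distribution approximation for n >= 10 and from exact enumeration
    of rank permutations below that (falling back to the approximation when
    ties make the exact null invalid). Constant input is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman: vectors must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman: need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman: constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n < 10 and not ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        p = _t_approx_p(np.array([rho]), n)[0]
    return CorrelationResult(rho=rho, p=float(min(p, 1.0)), n=n)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho*sqrt((n-2)/(1-rho^2))."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return np.minimum(p, 1.0)


def spearman_matrix(X: np.ndarray, Y: np.ndarray | None = None):
    """All-pairs Spearman between columns of X (and of Y), with t-approx p.

    Returns (rho, p); rho[i, j] correlates X[:, i] with Y[:, j] (or X with
    itself when Y is None). Constant columns yield rho = 0, p = 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    rx = stats.rankdata(X, axis=0)
    rx = rx - rx.mean(axis=0)
    sx = np.sqrt((rx ** 2).sum(axis=0))
    const_x = sx == 0
    sx[const_x] = 1.0
    rx = rx / sx
    if Y is None:
        rho = rx.T @ rx
        const_y = const_x
    else:
        Y = np.asarray(Y, dtype=float)
        ry = stats.rankdata(Y, axis=0)
        ry = ry - ry.mean(axis=0)
        sy = np.sqrt((ry ** 2).sum(axis=0))
        const_y = sy == 0
        sy[const_y] = 1.0
        ry = ry / sy
        rho = rx.T @ ry
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = 0.0
    rho[:, const_y] = 0.0
    p = _t_approx_p(rho, n)
    p[const_x, :] = 1.0
    p[:, const_y] = 1.0
    return rho, p


def bray_curtis(abundance: np.ndarray, sample_ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a sample x feature matrix."""
    A = np.asarray(abundance, dtype=float)
    if (A < 0).any():
        raise ValueError("bray_curtis: negative abundance")
    if (A.sum(axis=1) == 0).any():
        raise ValueError("bray_curtis: all-zero sample row")
    d = squareform(pdist(A, metric="braycurtis"))
    ids = tuple(sample_ids) if sample_ids is not None else tuple(
        f"s{i}" for i in range(A.shape[0])
    )
    return DistanceMatrix(ids, d)


def _rank_condensed(d: DistanceMatrix) -> np.ndarray:
    return stats.rankdata(d.condensed())


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Spearman correlation of the two upper triangles.

    Significance by jointly permuting rows/columns of d2; one-sided
    (greater), add-one estimator.
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("mantel: mismatched sample ids")
    if n_perm < 99:
        raise ValueError("mantel: n_perm must be >= 99")
    n = len(d1.sample_ids)
    r1 = _rank_condensed(d1)
    r1 = (r1 - r1.mean()) / r1.std()
    iu = np.triu_indices(n, k=1)

    def corr(mat2: np.ndarray) -> float:
        r2 = stats.rankdata(mat2[iu])
        sd = r2.std()
        if sd == 0:
            return 0.0
        return float(np.mean(r1 * (r2 - r2.mean()) / sd))

    obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += corr(d2.values[np.ix_(perm, perm)]) >= obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return obs, float(p)


def _permanova_ss(d2_vals: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2_vals.shape[0]
    ss_total = d2_vals.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        ss_within += d2_vals[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """One-way PERMANOVA: returns (R2, F, p).

    R2 = SS_between / SS_total from the squared-distance partition
    (equivalent to the Gower-centred decomposition); p by label permutation
    with the add-one estimator.
    """
    labels = np.asarray(groups)
    if labels.size != len(d.sample_ids):
        raise ValueError("permanova: label length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("permanova: need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("permanova: every group needs >= 2 samples")
    n, k = labels.size, uniq.size
    d2_vals = d.values ** 2

    def f_stat(lab: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2_vals, lab)
        ss_between = ss_total - ss_within
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        denom = ss_within / (n - k)
        f = (ss_between / (k - 1)) / denom if denom > 0 else np.inf
        return r2, f

    r2_obs, f_obs = f_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, f_perm = f_stat(labels[rng.permutation(n)])
        hits += f_perm >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return float(r2_obs), float(f_obs), float(p)


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if (c < 0).any() or not (c > 0).any():
        raise ValueError("chao1: need non-negative counts with >= 1 nonzero")
    return float(skbio_alpha.chao1(c.astype(int), bias_corrected=True))


def shannon(counts) -> float:
    """Shannon entropy (natural log) of the relative-abundance vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any() or not (c > 0).any():
        raise ValueError("shannon: need non-negative counts with >= 1 nonzero")
    return float(skbio_alpha.shannon(c, base=np.e))


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending, negatives included
    proportion_explained: np.ndarray  # over the positive part of the spectrum


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling (PCoA) of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and keeps coordinates for the
    positive eigenvalues; negative eigenvalues (non-Euclidean input) are
    reported, never silently dropped.
    """
    n = len(d.sample_ids)
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d.values ** 2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else evals[pos]
    frame = pd.DataFrame(
        coords,
        index=list(d.sample_ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(frame, evals, prop)
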