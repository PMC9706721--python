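"""Negative-binomial GLM likelihood-ratio differential abundance.

Raw counts are modelled (normalization enters through log(libsize * TMM
factor) offsets, the statistically correct use of the scaling factors).
A single common dispersion is estimated for all ASVs by maximizing the
Cox-Reid adjusted profile likelihood; each ASV is then tested with a
likelihood-ratio test of the treatment factor (full model: one mean per
group; reduced: intercept only) against chi-square with (#groups - 1)
degrees of freedom, followed by Benjamini-Hochberg FDR control.

The design is a single treatment factor (any-difference test); a
significant ASV is attributed to the group where its fitted mean is
maximal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data_model import CountTable
from .normalization import NormFactors

log = logging.getLogger(__name__)

MIN_TOTAL_COUNT = 5  # ASVs below this total are excluded from testing
MAX_ITER = 50
BETA_TOL = 1e-10
_BETA_MIN, _BETA_MAX = -50.0, 50.0


@dataclass(frozen=True)
class DiffAbundResult:
    asv_id: str
    log2fc: dict[str, float]  # per non-reference group, vs reference
    lrt: float
    df: int
    p: float
    fdr: float
    max_group: str  # group with the largest fitted mean
    converged: bool = True


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB2 (var = mu + phi*mu^2) log-likelihood; Poisson at phi=0."""
    mu = np.maximum(mu, 1e-10)
    if phi <= 0:
        return y * np.log(mu) - mu - special.gammaln(y + 1.0)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def _fisher_fit(
    counts: np.ndarray,  # asv x sample
    offsets: np.ndarray,  # sample log offsets
    one_hot: np.ndarray,  # sample x group membership (intercept: single column)
    phi: float,
):
    """Fisher scoring for the group-means NB GLM, vectorized over ASVs.

    Returns (beta [asv x group], mu [asv x sample], info [asv x group],
    converged [asv]). The log-link group-means design makes each
    coefficient a one-dimensional concave problem.
    """
    exp_off = np.exp(offsets)  # sample
    denom = exp_off @ one_hot  # group
    num = counts @ one_hot  # asv x group
    beta = np.log(np.maximum(num, 0.5) / denom)
    beta = np.clip(beta, _BETA_MIN, _BETA_MAX)
    converged = np.zeros(counts.shape[0], dtype=bool)
    mu = np.empty_like(counts, dtype=float)
    info = np.empty_like(beta)
    for _ in range(MAX_ITER):
        mu = np.exp(beta @ one_hot.T + offsets)
        w = mu / (1.0 + phi * mu)
        score = ((counts - mu) / (1.0 + phi * mu)) @ one_hot
        info = w @ one_hot
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.clip(beta + step, _BETA_MIN, _BETA_MAX)
        converged = np.max(np.abs(step), axis=1) < BETA_TOL
        if converged.all():
            break
    mu = np.exp(beta @ one_hot.T + offsets)
    w = mu / (1.0 + phi * mu)
    info = w @ one_hot
    return beta, mu, info, converged


def _prepare(table: CountTable, factors: NormFactors, groups) -> tuple:
    counts = table.counts().astype(float)
    labels = np.asarray([groups[s] for s in table.sample_ids])
    names = sorted(np.unique(labels))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    lab_idx = np.array([names.index(g) for g in labels])
    one_hot = np.eye(len(names))[lab_idx]
    lib = counts.sum(axis=0)
    offs = np.log(lib * factors.factors[table.sample_ids].to_numpy())
    return counts, offs, one_hot, names, lab_idx


def estimate_common_dispersion(
    table: CountTable, factors: NormFactors, groups
) -> float:
    """Common NB dispersion maximizing the Cox-Reid adjusted profile likelihood.

    The adjustment subtracts 0.5*log det(X'WX), which for the group-means
    design is 0.5 * sum of log per-group Fisher information. Search is on
    log10(dispersion) in [-6, 1]. ASVs with total count < MIN_TOTAL_COUNT
    are excluded.
    """
    counts, offs, one_hot, _, _ = _prepare(table, factors, groups)
    keep = counts.sum(axis=1) >= MIN_TOTAL_COUNT
    if not keep.any():
        raise ValueError("no ASV passes the low-count filter")
    counts = counts[keep]

    def neg_apl(log10_phi: float) -> float:
        phi = 10.0 ** log10_phi
        _, mu, info, _ = _fisher_fit(counts, offs, one_hot, phi)
        ll = _nb_loglik(counts, mu, phi).sum()
        cr = 0.5 * np.log(np.maximum(info, 1e-12)).sum()
        return -(ll - cr)

    res = optimize.minimize_scalar(
        neg_apl, bounds=(-6.0, 1.0), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(10.0 ** res.x)


def nb_lrt(
    table: CountTable,
    factors: NormFactors,
    groups,
    dispersion: float,
    reference: str | None = None,
) -> list[DiffAbundResult]:
    """Per-ASV NB likelihood-ratio test of the treatment factor.

    ``groups`` maps sample_id -> group name. Returns one result per tested
    ASV; ASVs below the low-count prefilter are excluded from testing and
    from the FDR denominator (logged).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    counts, offs, one_hot, names, _ = _prepare(table, factors, groups)
    asv_ids = np.array(table.asv_ids)
    keep = counts.sum(axis=1) >= MIN_TOTAL_COUNT
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("nb_lrt: excluded %d low-count ASV(s) (total < %d)",
                 n_drop, MIN_TOTAL_COUNT)
    counts, asv_ids = counts[keep], asv_ids[keep]
    if counts.shape[0] == 0:
        return []
    if reference is None:
        reference = "PD" if "PD" in names else names[0]
    ref_idx = names.index(reference)

    beta_full, mu_full, _, conv_full = _fisher_fit(counts, offs, one_hot, dispersion)
    ones = np.ones((counts.shape[1], 1))
    beta_red, mu_red, _, conv_red = _fisher_fit(counts, offs, ones, dispersion)
    ll_full = _nb_loglik(counts, mu_full, dispersion).sum(axis=1)
    ll_red = _nb_loglik(counts, mu_red, dispersion).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    df = len(names) - 1
    p = stats.chi2.sf(lrt, df)
    converged = conv_full & conv_red
    if not converged.all():
        log.warning("nb_lrt: %d ASV(s) failed to converge; p set to 1",
                    int((~converged).sum()))
        p = np.where(converged, p, 1.0)
    fdr = bh_adjust(p)
    max_group_idx = np.argmax(beta_full, axis=1)
    results = []
    for i, asv in enumerate(asv_ids):
        l2fc = {
            g: float((beta_full[i, j] - beta_full[i, ref_idx]) / np.log(2.0))
            for j, g in enumerate(names)
            if j != ref_idx
        }
        results.append(
            DiffAbundResult(
                asv_id=str(asv),
                log2fc=l2fc,
                lrt=float(lrt[i]),
                df=df,
                p=float(p[i]),
                fdr=float(fdr[i]),
                max_group=names[max_group_idx[i]],
                converged=bool(converged[i]),
            )
        )
    return results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def select_differential(results: list[DiffAbundResult], alpha: float = 0.05) -> set[str]:
    """ASVs with BH-adjusted p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return {r.asv_id for r in results if r.fdr < alpha}
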