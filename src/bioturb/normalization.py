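"""Library-size handling: TMM scaling factors and counts per million.

TMM (trimmed mean of M-values) estimates a relative scaling factor per
sample against a reference sample from the weighted mean of per-ASV log2
abundance ratios (M-values), after discarding the most extreme 30% of
M-values and 5% of average-abundance A-values. Weights are inverse
asymptotic (binomial) variances. Factors are rescaled to geometric mean 1,
so CPM columns remain comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable

M_TRIM = 0.30  # fraction of M-value extremes removed (total, both tails)
A_TRIM = 0.05  # fraction of A-value extremes removed (total, both tails)


@dataclass(frozen=True)
class NormFactors:
    factors: pd.Series  # sample_id -> positive scaling factor
    reference: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("non-positive TMM factor")
        log_gm = float(np.log(self.factors.to_numpy()).mean())
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors not rescaled to geometric mean 1")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


def _pair_factor(obs: np.ndarray, ref: np.ndarray) -> float:
    """Log2 TMM factor of one sample against the reference column."""
    n_obs, n_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    if o.size == 0:
        return 0.0
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # inverse asymptotic binomial variance of M
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    if np.max(np.abs(m)) < 1e-6:  # identical compositions
        return 0.0
    n = m.size
    # canonical TMM trim windows: the trim fraction is removed from EACH tail
    lo_m = int(np.floor(n * M_TRIM)) + 1
    hi_m = n - lo_m + 1
    lo_a = int(np.floor(n * A_TRIM)) + 1
    hi_a = n - lo_a + 1
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(table: CountTable) -> NormFactors:
    """TMM scaling factors for every sample of ``table``.

    The reference is the sample whose upper-quartile relative count is
    closest to the mean upper-quartile over samples. Raises on fewer than
    two samples.
    """
    counts = table.counts().astype(float)
    n_asv, n_samp = counts.shape
    if n_samp < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    uq = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    log2f = np.array([_pair_factor(counts[:, j], ref) for j in range(n_samp)])
    factors = 2.0 ** log2f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=table.sample_ids),
        reference=table.sample_ids[ref_idx],
    )


def cpm(
    table: CountTable,
    factors: NormFactors | None = None,
    log: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Counts per million, optionally TMM-scaled: count / (libsize * factor) * 1e6.

    With ``log=True`` a prior count is added and the result is
    log2-transformed (off by default; downstream screens are rank-based).
    """
    counts = table.data.astype(float)
    lib = counts.sum(axis=0)
    if factors is not None:
        missing = [s for s in table.sample_ids if s not in factors.factors.index]
        if missing:
            raise KeyError(f"missing TMM factor(s) for sample(s): {missing}")
        lib = lib * factors.factors[table.sample_ids].to_numpy()
    out = counts.div(lib, axis=1) * 1e6
    if log:
        out = np.log2(out + prior)
    return out
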