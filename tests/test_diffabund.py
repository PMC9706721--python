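"""NB-LRT differential abundance: GLM oracles, BH, boundaries."""

import numpy as np
import pandas as pd
import pytest

from bioturb.data_model import CountTable
from bioturb.diffabund import (
    DiffAbundResult,
    bh_adjust,
    estimate_common_dispersion,
    nb_lrt,
    select_differential,
)
from bioturb.normalization import NormFactors, tmm_factors


def _setup(counts, n_groups=3, per=10):
    counts = np.asarray(counts)
    cols = [f"s{j}" for j in range(counts.shape[1])]
    t = CountTable(pd.DataFrame(counts, index=[f"a{i}" for i in range(counts.shape[0])],
                                columns=cols))
    names = ["A", "B", "C"][:n_groups]
    groups = {c: names[j // per] for j, c in enumerate(cols)}
    return t, tmm_factors(t), groups


def test_constant_asv_across_equal_groups_is_null():
    counts = np.vstack([np.full(30, 17), np.random.default_rng(0).poisson(40, 30) + 1])
    t, nf, groups = _setup(counts)
    nf = NormFactors(pd.Series(1.0, index=t.sample_ids), reference="s0")
    lib = t.library_sizes()
    # identical counts with identical offsets: force equal library sizes
    equal = np.vstack([np.full(30, 17), np.full(30, 40)])
    t2 = CountTable(pd.DataFrame(equal, index=["a0", "a1"], columns=t.sample_ids))
    res = nb_lrt(t2, nf, groups, dispersion=0.1)
    r = res[0]
    assert r.lrt == pytest.approx(0.0, abs=1e-8)
    assert r.p == pytest.approx(1.0, abs=1e-8)
    assert all(abs(v) < 1e-6 for v in r.log2fc.values())


def test_poisson_limit_matches_statsmodels():
    """At dispersion 0 the LRT equals the Poisson GLM deviance difference."""
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    counts = rng.poisson(50, size=(10, 30))
    counts[0, 10:20] += rng.poisson(60, 10)
    t, nf, groups = _setup(counts)
    res = nb_lrt(t, nf, groups, dispersion=0.0)
    off = np.log(t.library_sizes().to_numpy() * nf.factors.to_numpy())
    labels = [groups[s] for s in t.sample_ids]
    X = pd.get_dummies(pd.Series(labels)).to_numpy(float)
    for r, y in zip(res, counts.astype(float)):
        full = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        red = sm.GLM(y, np.ones((30, 1)), family=sm.families.Poisson(), offset=off).fit()
        assert r.lrt == pytest.approx(2 * (full.llf - red.llf), abs=1e-6)


def test_nb_fit_matches_statsmodels_at_fixed_dispersion():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(5, 0.1, size=(5, 30)) + 1
    t, nf, groups = _setup(counts)
    phi = 0.15
    res = nb_lrt(t, nf, groups, dispersion=phi)
    off = np.log(t.library_sizes().to_numpy() * nf.factors.to_numpy())
    labels = [groups[s] for s in t.sample_ids]
    X = pd.get_dummies(pd.Series(labels)).to_numpy(float)
    y = counts[0].astype(float)
    full = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi), offset=off).fit()
    red = sm.GLM(y, np.ones((30, 1)), family=sm.families.NegativeBinomial(alpha=phi),
                 offset=off).fit()
    assert res[0].lrt == pytest.approx(2 * (full.llf - red.llf), abs=1e-5)


def test_lrt_invariant_to_reference_relabeling():
    rng = np.random.default_rng(4)
    counts = rng.poisson(30, size=(6, 30)) + 1
    t, nf, groups = _setup(counts)
    r1 = nb_lrt(t, nf, groups, 0.1, reference="A")
    r2 = nb_lrt(t, nf, groups, 0.1, reference="C")
    for a, b in zip(r1, r2):
        assert a.lrt == pytest.approx(b.lrt, abs=1e-8)
        assert a.p == pytest.approx(b.p, abs=1e-10)


def test_dispersion_recovery():
    """Cox-Reid common dispersion: near 0 for Poisson data, near truth for
    NB data (within +-25%)."""
    rng = np.random.default_rng(5)
    base = rng.lognormal(3.5, 1.0, size=500)
    mu = np.outer(base, np.ones(30))
    phi = 0.2
    r = 1 / phi
    y_nb = rng.negative_binomial(r, r / (r + mu))
    t, nf, groups = _setup(y_nb)
    est = estimate_common_dispersion(t, nf, groups)
    assert 0.15 <= est <= 0.25
    y_pois = rng.poisson(mu)
    t2, nf2, _ = _setup(y_pois)
    assert estimate_common_dispersion(t2, nf2, groups) <= 0.01


def test_low_count_and_degenerate_asvs_excluded():
    counts = np.vstack([np.zeros(30, int), np.ones(30, int),
                        np.random.default_rng(6).poisson(50, 30)])
    counts[1, 0] = 1  # total 30 >= threshold? ones row total=30 -> kept
    counts[0, 0] = 2  # total 2 < 5 -> dropped
    t, nf, groups = _setup(counts)
    res = nb_lrt(t, nf, groups, dispersion=0.1)
    assert {r.asv_id for r in res} == {"a1", "a2"}
    est = estimate_common_dispersion(t, nf, groups)  # no crash
    assert est >= 0


def test_bh_matches_stepup_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(5):
        p = rng.uniform(size=40)
        mine = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        # monotone in p after step-up
        order = np.argsort(p)
        assert (np.diff(mine[order]) >= -1e-12).all()
        assert (mine >= p - 1e-12).all()


def test_select_differential_boundaries():
    mk = lambda a, fdr: DiffAbundResult(a, {}, 1.0, 2, fdr, fdr, "A")
    res = [mk("a", 0.049), mk("b", 0.05), mk("c", 0.2)]
    assert select_differential(res, 0.05) == {"a"}
    assert select_differential([], 0.05) == set()
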