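"""Screening statistics against closed forms, brute force and scikit-bio."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioturb.assoc_stats import (
    DistanceMatrix,
    bray_curtis,
    chao1,
    mantel,
    pcoa,
    permanova,
    shannon,
    spearman,
    spearman_matrix,
)


# ---------------------------------------------------------------------- spearman
@pytest.mark.parametrize(
    "x,y,rho",
    [
        ([1, 2, 3, 4, 5], [2, 4, 9, 16, 100], 1.0),       # monotone
        ([1, 2, 3], [3, 1, 2], -0.5),                     # 1 - 6*6/(3*8)
        ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),           # antitone
    ],
)
def test_spearman_rank_formula(x, y, rho):
    assert spearman(x, y).rho == pytest.approx(rho, abs=1e-12)


def test_spearman_errors():
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2, 3, 4])


def test_spearman_t_approx_matches_scipy():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(1)
    x, y = rng.normal(size=30), rng.normal(size=30)
    mine = spearman(x, y)
    ref = spearmanr(x, y)
    assert mine.rho == pytest.approx(ref.statistic, abs=1e-12)
    assert mine.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_exact_small_n():
    """Below n=10 the p-value is an exact permutation tail probability."""
    x = [1, 2, 3, 4, 5]
    y = [1, 2, 3, 5, 4]
    res = spearman(x, y)
    # brute force over all 120 permutations
    null = []
    base = np.array(x, float)
    for perm in itertools.permutations(range(5)):
        null.append(abs(np.corrcoef(base, np.array(y, float)[list(perm)])[0, 1]))
    expected = np.mean(np.array(null) >= abs(res.rho) - 1e-12)
    assert res.p == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_spearman_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    r1 = spearman(x, y).rho
    r2 = spearman(np.exp(x), y).rho          # strictly increasing transform
    r3 = spearman(x, -np.exp(-y)).rho        # strictly increasing transform
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert r1 == pytest.approx(r3, abs=1e-12)


def test_spearman_matrix_agrees_with_scalar():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 3))
    Y = rng.normal(size=(20, 2))
    rho, p = spearman_matrix(X, Y)
    for i in range(3):
        for j in range(2):
            s = spearman(X[:, i], Y[:, j])
            assert rho[i, j] == pytest.approx(s.rho, abs=1e-12)


# ------------------------------------------------------------------ bray-curtis
def test_bray_curtis_formula_and_limits():
    a = np.array([[6, 2, 0], [2, 2, 2], [6, 2, 0], [0, 0, 5]], float)
    d = bray_curtis(a)
    assert d.values[0, 1] == pytest.approx(6 / 14)
    assert d.values[0, 2] == 0.0
    assert d.values[0, 3] == 1.0  # disjoint support
    assert np.allclose(d.values, d.values.T)
    with pytest.raises(ValueError):
        bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]))


# ----------------------------------------------------------------------- mantel
def _dist_from_points(points, ids=None):
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        tuple(ids or [f"s{i}" for i in range(len(points))]),
        squareform(pdist(np.asarray(points, float))),
    )


def test_mantel_self_comparison():
    rng = np.random.default_rng(3)
    d = _dist_from_points(rng.normal(size=(8, 2)))
    r, p = mantel(d, d, n_perm=199, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p == pytest.approx(1 / 200)


def test_mantel_exhaustive_four_samples():
    """p matches exhaustive enumeration of all 24 joint permutations."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(4)
    d1 = _dist_from_points(rng.normal(size=(4, 2)))
    d2 = _dist_from_points(rng.normal(size=(4, 2)))
    iu = np.triu_indices(4, 1)
    obs = spearmanr(d1.values[iu], d2.values[iu]).statistic
    hits = 0
    perms = list(itertools.permutations(range(4)))
    for perm in perms:
        m = d2.values[np.ix_(perm, perm)]
        hits += spearmanr(d1.values[iu], m[iu]).statistic >= obs - 1e-12
    exact = hits / len(perms)
    # estimate with many permutations converges to the exhaustive value
    r, p = mantel(d1, d2, n_perm=4999, seed=1)
    assert r == pytest.approx(obs, abs=1e-12)
    assert p == pytest.approx(exact, abs=0.03)


def test_mantel_seed_reproducibility_and_errors():
    rng = np.random.default_rng(5)
    d1 = _dist_from_points(rng.normal(size=(6, 2)))
    d2 = _dist_from_points(rng.normal(size=(6, 2)))
    assert mantel(d1, d2, 199, seed=7) == mantel(d1, d2, 199, seed=7)
    d3 = _dist_from_points(rng.normal(size=(6, 2)), ids=list("abcdef"))
    with pytest.raises(ValueError):
        mantel(d1, d3, 199, seed=0)


# -------------------------------------------------------------------- permanova
def test_permanova_direct_sum_of_squares():
    """6-sample toy: R2 equals the direct squared-distance partition."""
    pts = np.array([[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [6, 5]], float)
    d = _dist_from_points(pts)
    groups = ["g1"] * 3 + ["g2"] * 3
    r2, f, p = permanova(d, groups, n_perm=199, seed=0)
    d2 = d.values ** 2
    n = 6
    ss_total = d2.sum() / (2 * n)
    ss_within = d2[:3, :3].sum() / 6 + d2[3:, 3:].sum() / 6
    assert r2 == pytest.approx(1 - ss_within / ss_total, abs=1e-12)
    # with groups of 3 only 20 distinct label splits exist, so the
    # smallest attainable permutation p is about 2/20
    assert p <= 0.15


def test_permanova_matches_skbio():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.distance import permanova as skbio_permanova

    rng = np.random.default_rng(6)
    pts = rng.normal(size=(12, 3))
    pts[6:] += 1.0
    d = _dist_from_points(pts)
    groups = ["a"] * 6 + ["b"] * 6
    r2, f, p = permanova(d, groups, n_perm=999, seed=0)
    ref = skbio_permanova(SkbioDM(d.values, ids=list(d.sample_ids)),
                          grouping=list(groups), permutations=999)
    assert f == pytest.approx(float(ref["test statistic"]), rel=1e-9)


def test_permanova_extreme_separation_and_errors():
    pts = np.vstack([np.random.default_rng(7).normal(size=(4, 2)) * 0.01,
                     np.random.default_rng(8).normal(size=(4, 2)) * 0.01 + 100])
    d = _dist_from_points(pts)
    r2, _, _ = permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
    assert r2 > 0.99
    with pytest.raises(ValueError):
        permanova(d, ["a"] * 7 + ["b"], n_perm=99, seed=0)


# -------------------------------------------------------------- alpha diversity
def test_chao1_closed_form():
    assert chao1([5, 5, 5]) == 3.0  # no singletons
    # S_obs=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
    assert chao1([1, 1, 2, 3, 4]) == pytest.approx(5.5)
    with pytest.raises(ValueError):
        chao1([0, 0])


def test_shannon_equal_counts():
    assert shannon([7, 7, 7, 7]) == pytest.approx(np.log(4))


# ------------------------------------------------------------------------- pcoa
def test_pcoa_symmetry_and_line():
    d3 = DistanceMatrix(("a", "b", "c"),
                        np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
    res = pcoa(d3)
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])
    line = _dist_from_points([[0], [1], [2], [5]])
    res2 = pcoa(line)
    assert res2.proportion_explained[0] == pytest.approx(1.0)


def test_pcoa_euclidean_roundtrip_and_skbio():
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(9)
    pts = rng.normal(size=(10, 2))
    d = _dist_from_points(pts)
    res = pcoa(d)
    rebuilt = squareform(pdist(res.coordinates.to_numpy()))
    assert np.allclose(rebuilt, d.values, atol=1e-8)

    import warnings
    from skbio.stats.ordination import pcoa as skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = skbio_pcoa(d.values)
    mine = np.sort(res.eigenvalues[res.eigenvalues > 1e-8])
    theirs = np.sort(np.asarray(ref.eigvals))
    theirs = theirs[theirs > 1e-8]
    assert np.allclose(mine, theirs, atol=1e-8)
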