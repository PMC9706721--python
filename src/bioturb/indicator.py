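"""Indicator species analysis (IndVal with group combinations).

For every ASV and every candidate combination c of treatment groups,
specificity A is the group-mean-corrected concentration of the ASV in c
(means, not sums, so unbalanced groups do not bias A), fidelity B is the
occurrence fraction within c, and the indicator statistic is sqrt(A*B).
Significance of the best combination comes from permuting group labels
over samples.

Specificity uses depth-corrected abundances (TMM-CPM); fidelity uses raw
presence (count > 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data_model import CountTable
from .normalization import cpm, tmm_factors


@dataclass(frozen=True)
class IndicatorResult:
    asv_id: str
    best_combo: tuple[str, ...]
    A: float
    B: float
    stat: float
    p: float


def _combos(group_names: list[str], max_combo_size: int) -> list[tuple[int, ...]]:
    k = len(group_names)
    out = []
    for size in range(1, min(max_combo_size, k) + 1):
        for c in itertools.combinations(range(k), size):
            if len(c) == k:
                continue  # the full set carries no indicator information
            out.append(c)
    return out


def _best_stats(
    abund: np.ndarray,  # asv x sample (depth-corrected)
    pres: np.ndarray,  # asv x sample boolean
    labels: np.ndarray,  # sample -> group index
    combos: list[tuple[int, ...]],
    n_groups: int,
):
    """Per-ASV best combination and its (A, B, stat) under one labelling."""
    one_hot = np.eye(n_groups)[labels]  # sample x group
    sizes = one_hot.sum(axis=0)
    means = (abund @ one_hot) / sizes  # asv x group
    occ = pres.astype(float) @ one_hot  # asv x group occurrence counts
    total_mean = means.sum(axis=1)
    safe_total = np.where(total_mean > 0, total_mean, 1.0)
    best_stat = np.zeros(abund.shape[0])
    best_idx = np.zeros(abund.shape[0], dtype=int)
    best_a = np.zeros(abund.shape[0])
    best_b = np.zeros(abund.shape[0])
    for ci, c in enumerate(combos):
        c = list(c)
        a = means[:, c].sum(axis=1) / safe_total
        b = occ[:, c].sum(axis=1) / sizes[c].sum()
        stat = np.sqrt(a * b)
        better = stat > best_stat + 1e-15
        best_stat = np.where(better, stat, best_stat)
        best_idx = np.where(better, ci, best_idx)
        best_a = np.where(better, a, best_a)
        best_b = np.where(better, b, best_b)
    return best_stat, best_idx, best_a, best_b


def indval(
    table: CountTable,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    max_combo_size: int = 2,
    abundance: np.ndarray | None = None,
) -> list[IndicatorResult]:
    """IndVal over group combinations with permutation significance.

    ``groups`` maps sample_id -> group name. ``abundance`` overrides the
    default TMM-CPM matrix used for specificity (asv x sample, same order
    as the table). p = (1 + #{permuted best stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("indval: n_perm must be >= 99")
    sample_ids = table.sample_ids
    group_names = sorted({groups[s] for s in sample_ids})
    if len(group_names) < 2:
        raise ValueError("indval: need >= 2 groups")
    labels = np.array([group_names.index(groups[s]) for s in sample_ids])
    counts_per_group = np.bincount(labels, minlength=len(group_names))
    if (counts_per_group == 0).any():
        raise ValueError("indval: a group has 0 samples")
    if abundance is None:
        abundance = cpm(table, tmm_factors(table)).to_numpy()
    abund = np.asarray(abundance, dtype=float)
    pres = table.counts() > 0
    combos = _combos(group_names, max_combo_size)
    obs_stat, obs_idx, obs_a, obs_b = _best_stats(
        abund, pres, labels, combos, len(group_names)
    )
    rng = np.random.default_rng(seed)
    hits = np.zeros(abund.shape[0])
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(labels.size)]
        perm_stat, _, _, _ = _best_stats(
            abund, pres, perm_labels, combos, len(group_names)
        )
        hits += perm_stat >= obs_stat - 1e-12
    p = (1.0 + hits) / (1.0 + n_perm)
    results = []
    for i, asv in enumerate(table.asv_ids):
        combo = tuple(group_names[g] for g in combos[obs_idx[i]])
        results.append(
            IndicatorResult(
                asv_id=asv,
                best_combo=combo,
                A=float(obs_a[i]),
                B=float(obs_b[i]),
                stat=float(obs_stat[i]),
                p=float(p[i]),
            )
        )
    return results


def select_iasv(
    results: list[IndicatorResult], alpha: float = 0.05
) -> dict[str, set[str]]:
    """Indicator ASVs per group: p < alpha, assigned to every group in the
    best combination (an ASV indicating a pair of groups appears under both)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    out: dict[str, set[str]] = {}
    for r in results:
        if r.p < alpha:
            for g in r.best_combo:
                out.setdefault(g, set()).add(r.asv_id)
    return out
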