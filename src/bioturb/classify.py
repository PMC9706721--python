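"""The response-classification cascade and its summary statistics.

pASV: parameter-driven ASVs (Mantel-gated Spearman screen against
fermentation parameters). iASV: indicator ASVs positively associated with
one or more treatment types. brASV = iASV minus pASV: affected by the
inoculation rather than the process. bsASV = brASV supported by the
NB-LRT differential test at FDR < 0.05. eASV: activity-linked ASVs at
MIC >= 0.35 (strong at >= 0.55). bsModules: top-ranked network modules
holding a substantial share of bsASV nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_stats import bray_curtis, mantel, spearman_matrix
from .data_model import ACTIVITIES, PARAMETERS, CountTable, SampleInfo, metadata_to_frame
from .network import CooccurrenceNetwork

log = logging.getLogger(__name__)


@dataclass
class AsvClassification:
    """Per-ASV membership flags and statistics across the cascade."""

    asv_id: str
    kingdom: str
    is_pasv: bool = False
    driving_parameters: tuple[str, ...] = ()
    is_iasv: bool = False
    iasv_combo: tuple[str, ...] = ()
    iasv_stat: float = np.nan
    iasv_p: float = np.nan
    is_brasv: bool = False
    is_bsasv: bool = False
    bsasv_types: tuple[str, ...] = ()
    easv_activities: dict[str, float] = field(default_factory=dict)  # activity -> MIC
    strong_easv: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.is_brasv and (not self.is_iasv or self.is_pasv):
            raise ValueError(f"{self.asv_id}: brASV must be iASV and not pASV")
        if self.is_bsasv and not self.is_brasv:
            raise ValueError(f"{self.asv_id}: bsASV must be brASV")
        for a in self.strong_easv:
            if a not in self.easv_activities:
                raise ValueError(f"{self.asv_id}: strong eASV for non-eASV activity")


def identify_pasv(
    table: CountTable,
    meta: list[SampleInfo],
    rho_min: float = 0.60,
    alpha: float = 0.05,
    mantel_alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    per_type: bool = True,
) -> tuple[set[str], dict[str, tuple[str, ...]]]:
    """Parameter-driven ASVs.

    Parameters first pass a community-level gate: Mantel test between the
    Bray-Curtis community distance and the parameter's Euclidean distance
    (p < mantel_alpha). An ASV is a pASV iff, for at least one gated
    parameter, |Spearman rho| > rho_min with p < alpha; by default the
    screen runs within each treatment type separately (30 samples each)
    and an ASV qualifying in any type qualifies overall. Returns the pASV
    set and each pASV's driving parameter(s).
    """
    mf = metadata_to_frame(meta).loc[table.sample_ids]
    rel = table.counts().astype(float)
    rel = rel / rel.sum(axis=0)
    d_comm = bray_curtis(rel.T, table.sample_ids)
    gated = []
    for pi, param in enumerate(PARAMETERS):
        vals = mf[param].to_numpy()[:, None]
        d_param = bray_curtis_like_euclidean(vals, table.sample_ids)
        _, p = mantel(d_comm, d_param, n_perm=n_perm, seed=seed + pi)
        if p < mantel_alpha:
            gated.append(param)
    if not gated:
        log.warning("identify_pasv: no parameter passes the Mantel gate")
        return set(), {}

    drivers: dict[str, set[str]] = {}
    abund = table.counts().astype(float).T  # sample x asv
    asv_ids = np.array(table.asv_ids)

    def screen(rows: np.ndarray) -> None:
        X = abund[rows]
        Y = mf.iloc[rows][gated].to_numpy()
        rho, p = spearman_matrix(X, Y)
        hit = (np.abs(rho) > rho_min) & (p < alpha)
        for ai, pj in zip(*np.nonzero(hit)):
            drivers.setdefault(str(asv_ids[ai]), set()).add(gated[pj])

    if per_type:
        for t in sorted(mf["mtd_type"].unique()):
            screen(np.nonzero((mf["mtd_type"] == t).to_numpy())[0])
    else:
        screen(np.arange(len(mf)))
    return set(drivers), {a: tuple(sorted(s)) for a, s in drivers.items()}


def bray_curtis_like_euclidean(values: np.ndarray, ids):
    """Euclidean distance matrix over a sample x variable block (used for
    parameter-space distances in the Mantel gate)."""
    from scipy.spatial.distance import pdist, squareform

    from .assoc_stats import DistanceMatrix

    return DistanceMatrix(tuple(ids), squareform(pdist(np.asarray(values, float))))


def derive_brasv(
    iasv: dict[str, set[str]], pasv: set[str]
) -> dict[str, set[str]]:
    """brASV per type: indicator ASVs minus parameter-driven ASVs."""
    return {t: s - pasv for t, s in iasv.items()}


def derive_bsasv(
    brasv: dict[str, set[str]], differential: set[str]
) -> dict[str, set[str]]:
    """bsASV per type: brASV intersected with the NB-LRT differential set."""
    return {t: s & differential for t, s in brasv.items()}


def union(sets: dict[str, set[str]]) -> set[str]:
    out: set[str] = set()
    for s in sets.values():
        out |= s
    return out


def effect_size(bsasv: set[str], table: CountTable) -> float:
    """Bioturbation effect size: percentage of total raw sequence counts
    carried by the bsASVs."""
    unknown = bsasv - set(table.asv_ids)
    if unknown:
        raise ValueError(f"effect_size: ASV(s) not in table: {sorted(unknown)[:5]}")
    total = table.counts().sum()
    if not bsasv:
        return 0.0
    part = table.data.loc[sorted(bsasv)].to_numpy().sum()
    return float(100.0 * part / total)


def identify_bsmodules(
    net: CooccurrenceNetwork,
    bsasv: set[str],
    top_k: int = 10,
    min_share: float = 0.10,
) -> set[int]:
    """Bioturbation-sensitive modules: among the ``top_k`` largest modules,
    those holding at least ``min_share`` of all bsASV nodes present in the
    network."""
    bs_nodes = bsasv & set(net.nodes)
    if not bs_nodes:
        return set()
    top = net.top_modules(top_k)
    if len(net.modules()) < top_k:
        log.warning("identify_bsmodules: only %d modules available (top_k=%d)",
                    len(net.modules()), top_k)
    mods = net.modules()
    out = set()
    for mid in top:
        share = len(mods[mid] & bs_nodes) / len(bs_nodes)
        if share >= min_share:
            out.add(mid)
    return out


def identify_easv(
    mic: pd.DataFrame,  # ASV x activity MIC matrix
    threshold: float = 0.35,
    strong_threshold: float = 0.55,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Activity-linked ASVs: MIC >= threshold (inclusive), with a strong
    subset at MIC >= strong_threshold."""
    if not 0 < threshold <= strong_threshold <= 1:
        raise ValueError("need 0 < threshold <= strong_threshold <= 1")
    easv = {a: set(mic.index[mic[a] >= threshold]) for a in mic.columns}
    strong = {a: set(mic.index[mic[a] >= strong_threshold]) for a in mic.columns}
    return easv, strong


def effect_intensity(
    bsasv: set[str], easv: dict[str, set[str]]
) -> dict[str, float]:
    """Per activity: percentage of its eASVs that are also bsASVs; NaN
    (with a warning) when the activity has no eASVs."""
    out = {}
    for a, s in easv.items():
        if not s:
            log.warning("effect_intensity: no eASV for activity %s", a)
            out[a] = float("nan")
        else:
            out[a] = float(100.0 * len(s & bsasv) / len(s))
    return out


def easv_module_coverage(
    easv: dict[str, set[str]],
    bsmodules: set[int],
    net: CooccurrenceNetwork,
) -> dict[str, float]:
    """Per activity: percentage of its eASV network nodes that fall inside
    the bsModules; NaN when no eASV node is in the network."""
    mods = net.modules()
    bs_nodes: set[str] = set()
    for mid in bsmodules:
        bs_nodes |= mods.get(mid, set())
    out = {}
    node_set = set(net.nodes)
    for a, s in easv.items():
        in_net = s & node_set
        if not in_net:
            out[a] = float("nan")
        else:
            out[a] = float(100.0 * len(in_net & bs_nodes) / len(in_net))
    return out


def build_classification(
    kingdom: str,
    asv_ids: list[str],
    pasv: set[str],
    pasv_drivers: dict[str, tuple[str, ...]],
    indicator_results,
    iasv: dict[str, set[str]],
    brasv: dict[str, set[str]],
    bsasv: dict[str, set[str]],
    mic: pd.DataFrame | None = None,
    easv: dict[str, set[str]] | None = None,
    strong: dict[str, set[str]] | None = None,
) -> list[AsvClassification]:
    """Assemble and validate per-ASV cascade records."""
    ind_by_id = {r.asv_id: r for r in indicator_results}
    iasv_all = union(iasv)
    brasv_all = union(brasv)
    bsasv_all = union(bsasv)
    out = []
    for asv in asv_ids:
        rec = AsvClassification(asv_id=asv, kingdom=kingdom)
        rec.is_pasv = asv in pasv
        rec.driving_parameters = pasv_drivers.get(asv, ())
        if asv in ind_by_id:
            r = ind_by_id[asv]
            rec.iasv_stat, rec.iasv_p = r.stat, r.p
            if asv in iasv_all:
                rec.is_iasv = True
                rec.iasv_combo = r.best_combo
        rec.is_brasv = asv in brasv_all
        rec.is_bsasv = asv in bsasv_all
        rec.bsasv_types = tuple(sorted(t for t, s in bsasv.items() if asv in s))
        if mic is not None and asv in mic.index and easv is not None:
            rec.easv_activities = {
                a: float(mic.loc[asv, a]) for a in mic.columns if asv in easv.get(a, set())
            }
            rec.strong_easv = tuple(
                sorted(a for a in mic.columns if asv in (strong or {}).get(a, set()))
            )
        rec.validate()
        out.append(rec)
    return out


def classification_frame(records: list[AsvClassification]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "asv_id": r.asv_id,
                "kingdom": r.kingdom,
                "pASV": r.is_pasv,
                "driving_parameters": ",".join(r.driving_parameters),
                "iASV": r.is_iasv,
                "iasv_combo": ",".join(r.iasv_combo),
                "iasv_stat": r.iasv_stat,
                "iasv_p": r.iasv_p,
                "brASV": r.is_brasv,
                "bsASV": r.is_bsasv,
                "bsasv_types": ",".join(r.bsasv_types),
                "eASV": ",".join(sorted(r.easv_activities)),
                "strong_eASV": ",".join(r.strong_easv),
            }
        )
    return pd.DataFrame(rows).set_index("asv_id")
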