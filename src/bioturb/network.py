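"""Positive co-occurrence networks and module detection.

Edges connect ASV pairs whose Spearman correlation over samples exceeds a
positive threshold at a raw significance gate (default rho > 0.65,
p < 0.001; the gate is deliberately unadjusted). Modules come from greedy
(CNM) modularity maximization on the rho-weighted graph, which is
deterministic under the stable node ordering used here; module ids are
assigned by descending node count (M1 largest, ties by smallest member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .assoc_stats import spearman_matrix
from .data_model import CountTable, SampleInfo, metadata_to_frame

log = logging.getLogger(__name__)

MIN_TOTAL = 2  # keep ASVs with total count strictly above this
MIN_PREVALENCE = 4  # ... and nonzero in strictly more than this many samples


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph  # nodes: asv ids; edge attr "weight" = rho
    module_of: dict[str, int] = field(default_factory=dict)  # node -> module id (1 = largest)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mid in self.module_of.items():
            out.setdefault(mid, set()).add(node)
        return out

    def top_modules(self, k: int) -> list[int]:
        mods = self.modules()
        ranked = sorted(mods, key=lambda m: (-len(mods[m]), min(mods[m])))
        return ranked[:k]


def filter_for_network(table: CountTable) -> CountTable:
    """Network prefilter: total count > 2 and present in > 4 samples."""
    counts = table.counts()
    keep = (counts.sum(axis=1) > MIN_TOTAL) & ((counts > 0).sum(axis=1) > MIN_PREVALENCE)
    if not keep.any():
        raise ValueError(
            "network prefilter removed every ASV "
            f"(need total > {MIN_TOTAL} and prevalence > {MIN_PREVALENCE})"
        )
    return table.subset_asvs(list(np.array(table.asv_ids)[keep]))


def build_network(
    abundance: pd.DataFrame,
    rho_min: float = 0.65,
    p_max: float = 0.001,
) -> CooccurrenceNetwork:
    """Positive Spearman co-occurrence graph over the columns (ASVs) of a
    sample x ASV abundance matrix. Isolated nodes are retained; they later
    form singleton modules."""
    if abundance.shape[0] < 5:
        raise ValueError("build_network: need >= 5 samples")
    if abundance.shape[1] < 2:
        raise ValueError("build_network: need >= 2 ASVs")
    asv_ids = list(abundance.columns)
    rho, p = spearman_matrix(abundance.to_numpy())
    g = nx.Graph()
    g.add_nodes_from(asv_ids)
    iu, ju = np.triu_indices(len(asv_ids), k=1)
    hit = (rho[iu, ju] > rho_min) & (p[iu, ju] < p_max)
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(asv_ids[i], asv_ids[j], weight=float(rho[i, j]))
    return CooccurrenceNetwork(g)


def detect_modules(net: CooccurrenceNetwork, seed: int = 0) -> CooccurrenceNetwork:
    """Fill module assignments by greedy modularity maximization.

    The CNM agglomeration is deterministic for a fixed node order, so the
    seed is recorded for interface stability but does not change the
    result. Isolated nodes become singleton modules. Ids are 1-based by
    descending module size.
    """
    g = net.graph
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    core = g.subgraph([n for n in g.nodes if g.degree(n) > 0])
    communities: list[set[str]] = []
    if core.number_of_nodes() > 0:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(
            core, weight="weight"
        )]
    communities.extend({n} for n in isolated)
    communities.sort(key=lambda c: (-len(c), min(c)))
    net.module_of = {n: i + 1 for i, c in enumerate(communities) for n in sorted(c)}
    return net


def module_abundance(
    net: CooccurrenceNetwork,
    abundance: pd.DataFrame,  # sample x ASV (CPM)
    meta: list[SampleInfo],
    by: str = "type",
) -> pd.DataFrame:
    """Mean summed member CPM per module per stratum.

    ``by`` is one of "type", "phase", "type x phase". Module member CPM is
    summed within each sample, then averaged over the stratum's samples.
    """
    if not net.module_of:
        raise ValueError("module_abundance: modules not assigned")
    mf = metadata_to_frame(meta).loc[list(abundance.index)]
    strata = {
        "type": mf["mtd_type"],
        "phase": mf["phase"],
        "type x phase": mf["mtd_type"] + "/" + mf["phase"],
    }
    if by not in strata:
        raise ValueError(f"unknown stratification: {by!r}")
    labels = strata[by]
    records = []
    for mid, members in sorted(net.modules().items()):
        cols = [m for m in members if m in abundance.columns]
        per_sample = abundance[cols].sum(axis=1)
        for stratum, vals in per_sample.groupby(labels):
            records.append(
                {"module": mid, "stratum": stratum, "mean_cpm": float(vals.mean()),
                 "n_members": len(members)}
            )
    return pd.DataFrame(records)


def degree_abundance_profile(
    net: CooccurrenceNetwork,
    abundance: pd.DataFrame,  # sample x ASV (CPM)
    highlight: set[str] | None = None,
) -> pd.DataFrame:
    """Per-node degree and mean CPM with a highlight flag.

    Mirrors the degree-vs-abundance view used to show that responsive taxa
    concentrate in the low-degree, low-abundance corner of the network.
    Unknown highlight ids are warned about and skipped.
    """
    highlight = set(highlight or ())
    unknown = highlight - set(net.nodes)
    if unknown:
        log.warning("degree_abundance_profile: %d highlight id(s) not in network",
                    len(unknown))
        highlight -= unknown
    rows = []
    for node in net.nodes:
        mean_cpm = float(abundance[node].mean()) if node in abundance.columns else 0.0
        rows.append(
            {
                "asv_id": node,
                "degree": net.graph.degree(node),
                "mean_cpm": mean_cpm,
                "module": net.module_of.get(node, -1),
                "highlighted": node in highlight,
            }
        )
    return pd.DataFrame(rows).set_index("asv_id")


def profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Marginal medians of degree and CPM for highlighted nodes vs all."""
    groups = {"all": profile, "highlighted": profile[profile["highlighted"]]}
    rows = []
    for name, sub in groups.items():
        if len(sub) == 0:
            continue
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "median_degree": float(sub["degree"].median()),
                "median_cpm": float(sub["mean_cpm"].median()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
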