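"""Co-occurrence network: filters, edges, modules, summaries."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bioturb.data_model import CountTable
from bioturb.network import (
    CooccurrenceNetwork,
    build_network,
    degree_abundance_profile,
    detect_modules,
    filter_for_network,
    module_abundance,
    profile_summary,
)


def test_filter_rules():
    counts = np.zeros((4, 10), dtype=int)
    counts[0, :5] = 1          # total 5 > 2, prevalence 5 > 4 -> kept
    counts[1, :4] = 25         # total 100 in exactly 4 samples -> dropped
    counts[2, :2] = 1          # total 2 in 10 samples -> dropped (total rule)
    counts[3, :] = 3           # background row keeps every column nonzero
    df = pd.DataFrame(counts, index=["keep", "few_samples", "low_total", "bg"],
                      columns=[f"s{j}" for j in range(10)])
    out = filter_for_network(CountTable(df))
    assert out.asv_ids == ["keep", "bg"]
    nothing_passes = CountTable(pd.DataFrame([[1, 1]], index=["a"], columns=["s0", "s1"]))
    with pytest.raises(ValueError):
        filter_for_network(nothing_passes)


def test_build_network_edges_and_signs():
    rng = np.random.default_rng(0)
    n = 20
    base = rng.normal(size=n)
    ab = pd.DataFrame({
        "up1": base + rng.normal(0, 1e-6, n),
        "up2": base,
        "down": -base,
        "noise": rng.normal(size=n),
    }, index=[f"s{i}" for i in range(n)])
    net = build_network(ab, rho_min=0.65, p_max=0.001)
    edges = {frozenset((u, v)) for u, v, _ in net.edges}
    assert frozenset(("up1", "up2")) in edges
    assert frozenset(("up1", "down")) not in edges  # positive-only rule
    assert "noise" in net.nodes  # isolated nodes retained


def test_planted_blocks_match_pairwise_oracle():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(1)
    n = 30
    b1, b2 = rng.normal(size=n), rng.normal(size=n)
    cols = {}
    for i in range(4):
        cols[f"x{i}"] = b1 + rng.normal(0, 0.3, n)
    for i in range(4):
        cols[f"y{i}"] = b2 + rng.normal(0, 0.3, n)
    for i in range(4):
        cols[f"z{i}"] = rng.normal(size=n)
    ab = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    net = build_network(ab, rho_min=0.65, p_max=0.001)
    edges = {frozenset((u, v)) for u, v, _ in net.edges}
    expected = set()
    for a, b in itertools.combinations(ab.columns, 2):
        rho, p = spearmanr(ab[a], ab[b])
        if rho > 0.65 and p < 0.001:
            expected.add(frozenset((a, b)))
    assert edges == expected


def _brute_force_modularity(g):
    """Best weighted modularity over all partitions (tiny graphs only)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(c) for c in part], weight="weight")
        if q > best_q:
            best_q, best = q, [set(c) for c in part]
    return best, best_q


def test_modules_on_disjoint_cliques():
    g = nx.Graph()
    for offset in (0, 10):
        for u, v in itertools.combinations(range(offset, offset + 3), 2):
            g.add_edge(f"n{u}", f"n{v}", weight=1.0)
    net = detect_modules(CooccurrenceNetwork(g), seed=0)
    mods = net.modules()
    assert len(mods) == 2
    assert all(len(m) == 3 for m in mods.values())
    single = nx.complete_graph(4)
    single = nx.relabel_nodes(single, {i: f"c{i}" for i in range(4)})
    nx.set_edge_attributes(single, 1.0, "weight")
    assert len(detect_modules(CooccurrenceNetwork(single), seed=0).modules()) == 1


def test_modules_match_bruteforce_on_ring_of_cliques():
    """9-node ring of 3 triangles: greedy partition attains the exhaustive
    modularity optimum."""
    g = nx.ring_of_cliques(3, 3)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    net = detect_modules(CooccurrenceNetwork(g.copy()), seed=0)
    mine = list(net.modules().values())
    q_mine = nx.community.modularity(g, mine, weight="weight")
    _, q_best = _brute_force_modularity(g)
    assert q_mine == pytest.approx(q_best, abs=1e-12)


def test_module_ids_ranked_by_size_and_determinism():
    g = nx.Graph()
    for u, v in itertools.combinations("abcd", 2):
        g.add_edge(u, v, weight=1.0)
    for u, v in itertools.combinations("xyz", 2):
        g.add_edge(u, v, weight=1.0)
    g.add_node("lonely")
    net = detect_modules(CooccurrenceNetwork(g), seed=3)
    mods = net.modules()
    assert mods[1] == set("abcd")
    assert mods[2] == set("xyz")
    assert mods[3] == {"lonely"}
    net2 = detect_modules(CooccurrenceNetwork(g.copy()), seed=3)
    assert net.module_of == net2.module_of


def test_module_abundance_partition_property(toy_meta):
    samples = [s.sample_id for s in toy_meta]
    rng = np.random.default_rng(2)
    ab = pd.DataFrame(rng.uniform(1, 100, size=(len(samples), 5)),
                      index=samples, columns=list("abcde"))
    ab = ab.div(ab.sum(axis=1), axis=0) * 1e6  # CPM-like rows
    g = nx.Graph()
    g.add_nodes_from("abcde")
    g.add_edge("a", "b", weight=1.0)
    net = detect_modules(CooccurrenceNetwork(g), seed=0)
    tab = module_abundance(net, ab, toy_meta, by="type")
    # per stratum, module means sum to the stratum's mean total CPM (1e6)
    for _, sub in tab.groupby("stratum"):
        assert sub["mean_cpm"].sum() == pytest.approx(1e6)
    one_module = CooccurrenceNetwork(g.copy())
    one_module.module_of = {n: 1 for n in "abcde"}
    tab1 = module_abundance(one_module, ab, toy_meta, by="phase")
    assert np.allclose(tab1["mean_cpm"], 1e6)


def test_degree_abundance_profile_and_summary(caplog):
    g = nx.Graph()
    for u, v in itertools.combinations("abc", 2):
        g.add_edge(u, v, weight=1.0)
    g.add_node("iso")
    net = detect_modules(CooccurrenceNetwork(g), seed=0)
    ab = pd.DataFrame(
        {"a": [10, 10], "b": [20, 20], "c": [30, 30], "iso": [1, 1]},
        index=["s0", "s1"],
    )
    prof = degree_abundance_profile(net, ab, highlight={"iso", "ghost"})
    assert prof.loc["iso", "degree"] == 0
    assert (prof.loc[list("abc"), "degree"] == 2).all()
    assert prof.loc["iso", "highlighted"]
    assert "ghost" not in prof.index
    summ = profile_summary(prof)
    assert summ.loc["highlighted", "median_degree"] == 0
    assert summ.loc["all", "n"] == 4
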