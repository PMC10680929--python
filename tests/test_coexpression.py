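"""Co-expression networks, scale-free fitting, exposibility, core networks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_graph
from inflamnet.coexpression import (
    build_gcn,
    core_network,
    degree_histogram,
    edge_incident_subgraph,
    filter_by_exposibility,
    network_exposibility,
    powerlaw_fit,
    select_soft_power,
)
from inflamnet.diffexpr import ExpressionMatrix
from inflamnet.errors import InputError, UndefinedFitError


def expr(values: np.ndarray, genes=None) -> ExpressionMatrix:
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: ("case" if i < n_samples // 2 else "control") for i, s in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), groups)


def test_build_gcn_simple_correlation_structure():
    t = np.linspace(0, 1, 8)
    rng = np.random.default_rng(0)
    values = np.vstack([t, t + 0.0, rng.standard_normal(8)])
    values[1] = values[0]  # cor(g0, g1) = 1
    net = build_gcn(expr(values), power=2, weight_cutoff=0.9)
    assert net.has_edge("g0", "g1")
    assert net["g0"]["g1"]["weight"] == pytest.approx(1.0)
    assert net.number_of_edges() == 1


def test_build_gcn_unsigned_convention():
    t = np.linspace(0, 1, 8)
    values = np.vstack([t, -t, np.cos(20 * t)])
    net = build_gcn(expr(values), power=2, weight_cutoff=0.9)
    assert net["g0"]["g1"]["weight"] == pytest.approx(1.0)  # |cor| = 1 despite sign


def test_build_gcn_matches_bruteforce_pairwise_oracle():
    rng = np.random.default_rng(3)
    values = rng.standard_normal((30, 12))
    beta, cutoff = 3, 0.2
    net = build_gcn(expr(values), power=beta, weight_cutoff=cutoff)
    for i, j in itertools.combinations(range(30), 2):
        w = abs(np.corrcoef(values[i], values[j])[0, 1]) ** beta
        if w >= cutoff:
            assert net[f"g{i}"][f"g{j}"]["weight"] == pytest.approx(w, abs=1e-10)
        else:
            assert not net.has_edge(f"g{i}", f"g{j}")


def test_select_soft_power_smallest_satisfying_then_fallback():
    rng = np.random.default_rng(5)
    # two strong modules and background noise: higher powers look scale-free-ish
    factor = rng.standard_normal(20)
    values = np.vstack(
        [0.9 * factor + 0.4 * rng.standard_normal((10, 20)),
         rng.standard_normal((30, 20))]
    )
    res = select_soft_power(expr(values), candidate_powers=range(1, 8), target_r2=0.8)
    assert res.power in range(1, 8)
    assert set(res.fit_r2_by_power) == set(range(1, 8))
    if res.target_met:
        smaller = [b for b in res.fit_r2_by_power if b < res.power]
        assert all(res.fit_r2_by_power[b] < 0.8 for b in smaller)
    else:
        assert res.fit_r2_by_power[res.power] == max(res.fit_r2_by_power.values())


def test_powerlaw_fit_exact_histogram_and_errors():
    r2, slope = powerlaw_fit({1: 16, 2: 4, 4: 1})  # counts proportional to k^-2
    assert r2 == pytest.approx(1.0, abs=1e-9)
    assert slope == pytest.approx(-2.0, abs=1e-9)
    with pytest.raises(UndefinedFitError):
        powerlaw_fit({3: 10})


def test_exposibility_identities_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        g = random_graph(rng, 20)
        e = network_exposibility(g)
        assert 1.0 <= e <= g.number_of_nodes()
        if nx.is_connected(g):
            assert e == g.number_of_nodes()
    path = nx.path_graph(10)
    assert network_exposibility(path) == 10.0
    assert network_exposibility(nx.empty_graph(7)) == 1.0
    four_comps = nx.disjoint_union_all([nx.path_graph(5)] * 4)
    assert network_exposibility(four_comps) == 5.0
    with pytest.raises(InputError):
        network_exposibility(nx.Graph())


def test_filter_by_exposibility_boundary_inclusive():
    ten = nx.path_graph(10)  # exposibility 10.0
    frag = nx.disjoint_union_all([nx.path_graph(2)] * 5)  # 10 nodes, 5 comps -> 2.0
    assert filter_by_exposibility({"D1": ten, "D2": frag}, threshold=10) == {"D1"}
    assert filter_by_exposibility({"D2": frag}, threshold=10) == set()


def test_core_network_intersection_min_weight_and_symmetry():
    def g(edges):
        net = nx.Graph()
        for u, v, w in edges:
            net.add_edge(u, v, weight=w)
        return net

    g1 = g([("a", "b", 0.9), ("b", "c", 0.5), ("c", "d", 0.7)])
    g2 = g([("a", "b", 0.6), ("b", "c", 0.8)])
    g3 = g([("a", "b", 0.7), ("b", "c", 0.9), ("c", "e", 0.2)])
    core = core_network([g1, g2, g3])
    assert set(map(frozenset, core.edges())) == {frozenset("ab"), frozenset("bc")}
    assert set(core.nodes) == {"a", "b", "c"}
    assert core["a"]["b"]["weight"] == pytest.approx(0.6)  # min across inputs
    # order-independent and contained in every input
    for perm in itertools.permutations([g1, g2, g3]):
        alt = core_network(list(perm))
        assert set(map(frozenset, alt.edges())) == set(map(frozenset, core.edges()))
    for src in (g1, g2, g3):
        assert set(map(frozenset, core.edges())) <= set(map(frozenset, src.edges()))
    disjoint = core_network([g([("x", "y", 1.0)]), g([("p", "q", 1.0)])])
    assert disjoint.number_of_edges() == 0


def test_gcn_pipeline_degree_histogram_roundtrip(default_cohort):
    cohorts, _ = default_cohort
    net = edge_incident_subgraph(build_gcn(cohorts["D1"], power=6, weight_cutoff=0.1))
    hist = degree_histogram(net)
    assert sum(hist.values()) == net.number_of_nodes()
    assert all(d >= 1 for d in hist)
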