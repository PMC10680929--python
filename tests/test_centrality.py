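"""Centrality suite and weighted k-shell against independent oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    kshell_pruning_oracle,
    mann_whitney_oracle,
    random_graph,
)
from inflamnet.centrality import (
    centrality_correlation,
    centrality_table,
    compute_centralities,
    mann_whitney,
    top_fraction,
    weighted_kshell,
)
from inflamnet.errors import ConfigurationError, InputError, UndefinedFitError


def test_triangle_symmetry():
    table = compute_centralities(nx.complete_graph(["a", "b", "c"]))
    assert (table["degree"] == 2).all()
    assert (table["betweenness"] == 0).all()
    assert np.allclose(table["eigenvector"], 1.0)


def test_path_betweenness_and_information_series_resistance():
    table = compute_centralities(nx.path_graph(["a", "b", "c"]))
    assert table.loc["b", "betweenness"] == pytest.approx(1.0)
    assert table.loc["a", "betweenness"] == 0.0
    # series resistances: r(a,b)=1, r(a,c)=2 -> info(a)=3/3, info(b)=3/2
    assert table.loc["a", "information"] == pytest.approx(1.0)
    assert table.loc["c", "information"] == pytest.approx(1.0)
    assert table.loc["b", "information"] == pytest.approx(1.5)


def test_star_center_counts_leaf_pairs():
    table = compute_centralities(nx.star_graph(4))
    assert table.loc[0, "betweenness"] == pytest.approx(6.0)  # C(4,2) leaf pairs


def test_singleton_and_disconnected_conventions():
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.5)
    g.add_node("z")
    table = compute_centralities(g)
    assert table.loc["z", "information"] == 0.0
    assert table.loc["z", "eigenvector"] == 1.0  # max-normalized per component
    assert table.loc["a", "eigenvector"] == 1.0


def test_weighted_betweenness_prefers_strong_edges():
    # a-c direct (weak, length 10) vs a-b-c (strong, length 1+1): path via b wins
    g = nx.Graph()
    g.add_edge("a", "c", weight=0.1)
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    table = compute_centralities(g)
    assert table.loc["b", "betweenness"] == pytest.approx(1.0)


def test_kshell_classical_reduction_examples():
    shells, _ = weighted_kshell(nx.complete_graph(4))
    assert set(shells.values()) == {3}
    g = nx.complete_graph(3)
    g.add_edge(0, 99)  # pendant on a triangle
    shells, layers = weighted_kshell(g)
    assert shells[99] == 1
    assert all(shells[n] == 2 for n in (0, 1, 2))
    assert layers[99] == "outer" and layers[0] == "inner"


def test_weighted_kshell_matches_bruteforce_pruning_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        g = random_graph(rng, 12, weighted=True)
        shells, _ = weighted_kshell(g, alpha=0.5)
        assert shells == kshell_pruning_oracle(g, 0.5)
    with pytest.raises(ConfigurationError):
        weighted_kshell(nx.path_graph(3), alpha=1.5)


def test_centrality_table_invariants(default_cohort):
    cohorts, _ = default_cohort
    from inflamnet.coexpression import build_gcn, edge_incident_subgraph

    net = edge_incident_subgraph(build_gcn(cohorts["D1"], 6, 0.1))
    table = centrality_table(net)
    for comp in nx.connected_components(net):
        comp_max = table.loc[sorted(comp), "eigenvector"].max()
        assert comp_max == pytest.approx(1.0)
    assert table["shell_index"].max() >= table["shell_index"].min()
    assert set(table["layer"]) <= {"inner", "outer"}
    assert (table.loc[table["degree"] > 0, "information"] > 0).all()


def test_top_fraction_count_and_tie_rules():
    vals = {f"n{i:02d}": 1.0 for i in range(10)}
    assert top_fraction(vals, 0.5) == {f"n{i:02d}" for i in range(5)}  # lexicographic ties
    assert top_fraction({"a": 3, "b": 2, "c": 1}, 0.3) == {"a"}  # ceil(0.9) = 1
    assert top_fraction({"a": 3, "b": 2, "c": 1}, 0.6) == {"a", "b"}  # ceil(1.8) = 2
    forty = {f"n{i:02d}": float(i) for i in range(40)}
    assert len(top_fraction(forty, 0.05)) == 2


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.dictionaries(
        st.text(alphabet="abcdefgh", min_size=1, max_size=3),
        st.floats(allow_nan=False, allow_infinity=False, width=32),
        min_size=1,
        max_size=30,
    ),
    st.floats(min_value=0.01, max_value=1.0),
)
def test_top_fraction_size_is_ceil_and_rerun_stable(values, fraction):
    out = top_fraction(values, fraction)
    assert len(out) == int(np.ceil(fraction * len(values)))
    assert out == top_fraction(dict(reversed(values.items())), fraction)


def test_centrality_correlation_sign_and_threshold_rules():
    x = {f"n{i}": float(i) for i in range(10)}
    doubled = {k: 2 * v for k, v in x.items()}
    r, call = centrality_correlation(x, doubled)
    assert r == pytest.approx(1.0) and call
    negated = {k: -v for k, v in x.items()}
    r, call = centrality_correlation(x, negated)
    assert r == pytest.approx(-1.0) and not call
    rng = np.random.default_rng(0)
    weak = {k: 0.6 * v + 4 * rng.standard_normal() for k, v in x.items()}
    r, call = centrality_correlation(x, weak)
    if r * r < 0.5:
        assert not call
    with pytest.raises(UndefinedFitError):
        centrality_correlation(x, {k: 1.0 for k in x})
    with pytest.raises(InputError):
        centrality_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def test_mann_whitney_exact_and_degenerate_cases():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)
    _, p = mann_whitney([1.0], [1.0])
    assert p == 1.0


def test_mann_whitney_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = rng.permutation(20)[: rng.integers(2, 5)].astype(float)
        b = rng.permutation(40)[: rng.integers(2, 5)].astype(float) + 100.5
        pooled = np.concatenate([a, b])
        if len(np.unique(pooled)) != pooled.size:
            continue
        u, p = mann_whitney(a, b)
        u_o, p_o = mann_whitney_oracle(list(a), list(b))
        assert u == pytest.approx(u_o)
        assert p == pytest.approx(p_o, abs=1e-12)


def test_mann_whitney_null_simulation_is_well_behaved():
    rng = np.random.default_rng(2)
    big_p = 0
    for _ in range(100):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        _, p = mann_whitney(a, b)
        big_p += p > 0.01
    assert big_p >= 95
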