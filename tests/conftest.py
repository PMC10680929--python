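"""Shared fixtures and independent oracles.

Oracles here are deliberately naive re-derivations (exhaustive enumeration,
closed forms, brute-force pruning) kept independent of the library code they
check.
"""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np
import pytest

from inflamnet.simulate import CohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# oracles


def bh_stepup_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by explicit enumeration of all simple paths."""

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nb in graph.neighbors(node):
                if nb not in path:
                    stack.append((nb, path + [nb]))
        return paths

    score = {n: 0.0 for n in graph}
    nodes = sorted(graph)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            geodesics = [p for p in paths if len(p) == shortest]
            for p in geodesics:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(geodesics)
    return score


def eigenvector_oracle(graph: nx.Graph, iters: int = 20000) -> dict:
    """Max-normalized principal eigenvector by power iteration per component."""
    result = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) == 1:
            result[comp[0]] = 1.0
            continue
        adj = nx.to_numpy_array(graph, nodelist=comp, weight="weight")
        # shift guarantees the dominant eigenvalue is the largest in modulus
        shifted = adj + adj.sum() * np.eye(len(comp))
        vec = np.ones(len(comp))
        for _ in range(iters):
            nxt = shifted @ vec
            nxt /= np.linalg.norm(nxt)
            lam = float(nxt @ (shifted @ nxt))
            if np.linalg.norm(shifted @ nxt - lam * nxt) < 1e-13 * abs(lam):
                vec = nxt
                break
            vec = nxt
        vec = np.abs(vec)
        vec /= vec.max()
        result.update(zip(comp, vec.tolist()))
    return result


def effective_resistance_oracle(graph: nx.Graph, u, v) -> float:
    """r_eff(u, v) by grounding v and solving the reduced Laplacian system."""
    comp = sorted(nx.node_connected_component(graph, u))
    assert v in comp
    lap = nx.laplacian_matrix(graph, nodelist=comp, weight="weight").toarray()
    iu, iv = comp.index(u), comp.index(v)
    keep = [i for i in range(len(comp)) if i != iv]
    reduced = lap[np.ix_(keep, keep)]
    rhs = np.zeros(len(keep))
    rhs[keep.index(iu)] = 1.0
    potential = np.linalg.solve(reduced, rhs)
    return float(potential[keep.index(iu)])


def information_oracle(graph: nx.Graph) -> dict:
    """n_c / sum of pairwise effective resistances, via the grounded solver."""
    result = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        n_c = len(comp)
        if n_c == 1:
            result[comp[0]] = 0.0
            continue
        for u in comp:
            total = sum(
                effective_resistance_oracle(graph, u, v) for v in comp if v != u
            )
            result[u] = n_c / total
    return result


def kshell_pruning_oracle(graph: nx.Graph, alpha: float) -> dict:
    """Brute-force generalized-degree pruning, written independently."""
    alive = {n: True for n in graph}
    shells = {}

    def gdeg(node):
        nbrs = [m for m in graph.neighbors(node) if alive[m]]
        k = len(nbrs)
        if k == 0:
            return 0
        s = sum(graph[node][m].get("weight", 1.0) for m in nbrs)
        return round(k**alpha * s ** (1 - alpha))

    counter = 0
    while any(alive.values()):
        changed = True
        while changed:
            doomed = [n for n in graph if alive[n] and gdeg(n) <= counter]
            changed = bool(doomed)
            for n in doomed:
                shells[n] = counter
                alive[n] = False
        counter += 1
    return shells


def hypergeom_oracle(overlap: int, universe: int, term: int, study: int) -> float:
    """Closed-form upper-tail hypergeometric probability via binomials."""
    total = comb(universe, study)
    return sum(
        comb(term, j) * comb(universe - term, study - j)
        for j in range(overlap, min(term, study) + 1)
    ) / total


def mann_whitney_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group labelings."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(indices):
        grp = [pooled[i] for i in indices]
        rest = [pooled[i] for i in range(len(pooled)) if i not in indices]
        return sum(
            sum(1.0 if x > y else 0.5 if x == y else 0.0 for y in rest) for x in grp
        )

    observed = u_of(set(range(n_a)))
    us = [u_of(set(idx)) for idx in combinations(range(len(pooled)), n_a)]
    lo = sum(u <= observed for u in us) / len(us)
    hi = sum(u >= observed for u in us) / len(us)
    return observed, min(1.0, 2.0 * min(lo, hi))


def random_graph(rng: np.random.Generator, n_max: int, p: float = 0.4, *, connected=False, weighted=False) -> nx.Graph:
    """Random (optionally connected/weighted) labelled graph for property tests."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w = float(1.0 - rng.random()) if weighted else 1.0
                    g.add_edge(f"n{i}", f"n{j}", weight=w)
        if not connected or nx.is_connected(g):
            return g


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded draw of the default four-disease synthetic cohort."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def toy_weighted_graph():
    g = nx.Graph()
    g.add_weighted_edges_from(
        [("a", "b", 0.9), ("b", "c", 0.5), ("c", "d", 0.8), ("a", "c", 0.2)]
    )
    return g
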