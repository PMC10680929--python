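"""Centrality suite and weighted k-shell core decomposition.

Five measures drive protein prioritization:

* **degree** — number of interaction partners (hubs);
* **betweenness** — unnormalized shortest-path betweenness with edge length
  1/weight, so stronger interactions are shorter paths (bottlenecks);
* **eigenvector** — principal eigenvector of the weighted adjacency,
  max-normalized to 1 within each connected component;
* **information** — current-flow centrality from effective resistance: for a
  node i in a component of size n_c, information(i) = n_c / sum_j r_eff(i, j)
  with conductance equal to edge weight (singletons score 0);
* **weighted k-shell** — iterative pruning by the generalized degree
  k' = round(k**alpha * s**(1-alpha)) where k is degree and s weighted
  strength; nodes removed while k' <= the shell counter get that shell index.
  With uniform weights this reduces exactly to the classical k-core
  decomposition.  Shells in the top ``inner_fraction`` of the shell-index
  range form the network's inner core.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, UndefinedFitError

DEFAULT_ALPHA = 0.5
DEFAULT_INNER_FRACTION = 0.25
DEFAULT_TOP_FRACTION = 0.05
#: largest sample size for which the Mann-Whitney null is enumerated exactly
EXACT_MW_MAX_N = 12

CENTRALITY_COLUMNS = ("degree", "betweenness", "eigenvector", "information")


def _components(net: nx.Graph):
    return (sorted(c) for c in nx.connected_components(net))


def _eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Principal adjacency eigenvector, max-normalized per component."""
    result: dict[str, float] = {}
    for comp in _components(net):
        if len(comp) == 1:
            result[comp[0]] = 1.0
            continue
        adj = nx.to_numpy_array(net, nodelist=comp, weight="weight")
        eigvals, eigvecs = np.linalg.eigh(adj)
        vec = np.abs(eigvecs[:, -1])  # Perron vector of a connected component
        vec /= vec.max()
        result.update(zip(comp, vec.tolist()))
    return result


def _information_centrality(net: nx.Graph) -> dict[str, float]:
    """n_c / sum of effective resistances, per connected component."""
    result: dict[str, float] = {}
    for comp in _components(net):
        n_c = len(comp)
        if n_c == 1:
            result[comp[0]] = 0.0
            continue
        lap = nx.laplacian_matrix(net, nodelist=comp, weight="weight").toarray()
        lap_pinv = np.linalg.pinv(lap, hermitian=True)
        diag = np.diag(lap_pinv)
        r_eff = diag[:, None] + diag[None, :] - 2.0 * lap_pinv
        totals = r_eff.sum(axis=1)
        result.update(zip(comp, (n_c / totals).tolist()))
    return result


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, eigenvector and information centrality per node."""
    if net.number_of_nodes() == 0:
        raise InputError("cannot compute centralities on an empty network")
    lengths = {(u, v): 1.0 / d.get("weight", 1.0) for u, v, d in net.edges(data=True)}
    work = net.copy()
    nx.set_edge_attributes(work, lengths, "length")
    betweenness = nx.betweenness_centrality(work, weight="length", normalized=False)
    eigen = _eigenvector_centrality(net)
    info = _information_centrality(net)
    nodes = sorted(net.nodes)
    return pd.DataFrame(
        {
            "degree": [net.degree(n) for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "eigenvector": [eigen[n] for n in nodes],
            "information": [info[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _generalized_degree(net: nx.Graph, node, alpha: float) -> int:
    k = net.degree(node)
    s = sum(d.get("weight", 1.0) for _, _, d in net.edges(node, data=True))
    if k == 0:
        return 0
    return round(k**alpha * s ** (1.0 - alpha))


def weighted_kshell(
    net: nx.Graph,
    alpha: float = DEFAULT_ALPHA,
    inner_fraction: float = DEFAULT_INNER_FRACTION,
) -> tuple[dict[str, int], dict[str, str]]:
    """Shell index and inner/outer layer per node.

    Prunes nodes whose generalized degree k' = round(k**alpha * s**(1-alpha))
    is at most the current shell counter, recomputing k' after every removal
    so cascades stay within the counter, then increments the counter.  Layer
    is ``inner`` when the shell index reaches the top ``inner_fraction`` of
    the observed shell range (everyone is inner when all shells coincide).
    """
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha must lie in [0, 1]")
    if not 0 < inner_fraction <= 1:
        raise ConfigurationError("inner_fraction must lie in (0, 1]")
    if net.number_of_nodes() == 0:
        raise InputError("cannot decompose an empty network")

    work = net.copy()
    shells: dict[str, int] = {}
    counter = 0
    while work.number_of_nodes():
        removed_any = True
        while removed_any:
            doomed = [
                n for n in work.nodes if _generalized_degree(work, n, alpha) <= counter
            ]
            removed_any = bool(doomed)
            for n in doomed:
                shells[n] = counter
            work.remove_nodes_from(doomed)
        counter += 1

    s_min, s_max = min(shells.values()), max(shells.values())
    threshold = s_max - inner_fraction * (s_max - s_min)
    layers = {n: ("inner" if s >= threshold else "outer") for n, s in shells.items()}
    return shells, layers


def centrality_table(
    net: nx.Graph,
    alpha: float = DEFAULT_ALPHA,
    inner_fraction: float = DEFAULT_INNER_FRACTION,
) -> pd.DataFrame:
    """Full per-node record: four centralities plus shell index and layer."""
    table = compute_centralities(net)
    shells, layers = weighted_kshell(net, alpha=alpha, inner_fraction=inner_fraction)
    table["shell_index"] = [shells[n] for n in table.index]
    table["layer"] = [layers[n] for n in table.index]
    return table


def top_fraction(
    values: Mapping[str, float], fraction: float = DEFAULT_TOP_FRACTION
) -> set[str]:
    """The ceil(fraction * N) highest-valued nodes.

    Ties at the cut are broken by lexicographic node id so the result is a
    deterministic function of (values, ids).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    if not values:
        raise InputError("values is empty")
    k = int(np.ceil(fraction * len(values)))
    ranked = sorted(values, key=lambda n: (-values[n], n))
    return set(ranked[:k])


def centrality_correlation(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, bool]:
    """Pearson r over shared nodes; the relation is called positive iff
    r > 0 and r^2 >= 0.5."""
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise InputError("need at least 3 shared nodes")
    xs = np.array([x[n] for n in shared], float)
    ys = np.array([y[n] for n in shared], float)
    if xs.std() == 0 or ys.std() == 0:
        raise UndefinedFitError("zero variance in a centrality vector")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, bool(r > 0 and r * r >= 0.5)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution (full enumeration) when the pooled
    sample size is at most 12 and tie-free, and the tie-corrected normal
    approximation otherwise.  Two identical constant samples return p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    u_stat = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    if np.ptp(pooled) == 0:
        return u_stat, 1.0  # no information: every labeling is equally extreme
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
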