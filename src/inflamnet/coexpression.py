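"""Weighted co-expression networks, scale-free fitting, and the exposibility filter.

A gene co-expression network (GCN) is built the WGCNA way: the adjacency
between genes i and j is |pearson(x_i, x_j)|**beta for a soft-threshold power
beta, and an edge is kept when its adjacency weight clears a cutoff.  The
soft power is chosen as the smallest candidate whose connectivity
distribution fits a power law with r^2 at or above a target (scale-free
topology criterion).  Network "exposibility" — nodes divided by connected
components — scores how fragmented a network is; networks with exposibility
>= 10 are considered reliable enough for downstream interactome analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .diffexpr import ExpressionMatrix
from .errors import ConfigurationError, InputError, UndefinedFitError

logger = logging.getLogger(__name__)

#: reliability threshold on nodes / connected-components
EXPOSIBILITY_MIN = 10.0
#: scale-free fitness threshold on the power-law r^2
POWERLAW_R2_MIN = 0.5
DEFAULT_WEIGHT_CUTOFF = 0.1
DEFAULT_POWERS = tuple(range(1, 13))


@dataclass
class SoftPowerResult:
    power: int
    fit_r2_by_power: dict[int, float]
    target_met: bool


@dataclass
class GCNBuildReport:
    """Provenance of one disease GCN build."""

    network: nx.Graph
    chosen_power: int
    fit_r2_by_power: dict[int, float]
    weight_cutoff: float
    exposibility: float
    n_constant_genes_dropped: int = 0


def _correlation_matrix(mat: ExpressionMatrix) -> tuple[np.ndarray, list[str], int]:
    """|Pearson| matrix over non-constant genes; returns (abs corr, genes, n dropped)."""
    values = mat.values.to_numpy(float)
    keep = values.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d constant gene(s) from correlation", dropped)
    genes = [g for g, k in zip(mat.gene_ids, keep) if k]
    if len(genes) < 2:
        raise InputError("need at least 2 non-constant genes")
    corr = np.abs(np.corrcoef(values[keep]))
    np.fill_diagonal(corr, 0.0)
    return corr, genes, dropped


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """r^2 of the log-log regression of the connectivity distribution.

    Connectivity values are binned into equal-width bins; log10(count) is
    regressed on log10(mean connectivity) over non-empty bins.
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise UndefinedFitError("connectivity distribution has fewer than 2 distinct values")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    means = np.array([k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    ok = (counts > 0) & (means > 0)
    if ok.sum() < 2:
        raise UndefinedFitError("fewer than 2 non-empty connectivity bins")
    fit = stats.linregress(np.log10(means[ok]), np.log10(counts[ok]))
    return float(fit.rvalue**2)


def select_soft_power(
    mat: ExpressionMatrix,
    candidate_powers: Iterable[int] = DEFAULT_POWERS,
    target_r2: float = 0.8,
) -> SoftPowerResult:
    """Pick the smallest soft power whose network looks scale-free.

    For each candidate beta the soft adjacency a_ij = |cor|**beta is formed,
    per-gene connectivity k_i = sum_j a_ij computed, and the scale-free r^2 of
    the connectivity distribution measured.  Returns the smallest beta with
    r^2 >= target_r2; if none qualifies, the argmax-r^2 beta is returned with
    ``target_met=False``.
    """
    powers = sorted(set(int(p) for p in candidate_powers))
    if len(powers) < 2:
        raise ConfigurationError("need at least 2 candidate powers")
    if mat.values.shape[1] < 4:
        raise InputError("need at least 4 samples to estimate correlations")
    corr, _, _ = _correlation_matrix(mat)
    fits: dict[int, float] = {}
    for beta in powers:
        k = (corr**beta).sum(axis=1)
        try:
            fits[beta] = scale_free_fit(k)
        except UndefinedFitError:
            fits[beta] = 0.0
    for beta in powers:
        if fits[beta] >= target_r2:
            return SoftPowerResult(beta, fits, True)
    best = max(fits, key=lambda b: (fits[b], -b))
    logger.warning(
        "no candidate power reached scale-free r^2 >= %.2f; falling back to argmax %d",
        target_r2,
        best,
    )
    return SoftPowerResult(best, fits, False)


def build_gcn(
    mat: ExpressionMatrix, power: int, weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF
) -> nx.Graph:
    """Unsigned weighted co-expression network.

    Edge (i, j) with weight |pearson|**power is kept iff weight >=
    weight_cutoff.  All non-constant genes are retained as nodes, including
    isolates; reporting helpers count only edge-incident nodes.
    """
    if power < 1:
        raise ConfigurationError("power must be >= 1")
    if not 0 < weight_cutoff < 1:
        raise ConfigurationError("weight_cutoff must lie in (0, 1)")
    if len(mat.gene_ids) < 3:
        raise InputError("need at least 3 genes to build a co-expression network")
    corr, genes, _ = _correlation_matrix(mat)
    weights = corr**power
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(weights >= weight_cutoff, k=1))
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(weights[i, j])) for i, j in zip(ii, jj)
    )
    return graph


def edge_incident_subgraph(net: nx.Graph) -> nx.Graph:
    """The reported network: nodes with at least one edge."""
    keep = [n for n, d in net.degree() if d > 0]
    return net.subgraph(keep).copy()


def powerlaw_fit(degree_histogram: Mapping[int, int]) -> tuple[float, float]:
    """OLS fit of log10(count) on log10(degree) over non-zero bins.

    Returns (r^2, slope).  Used to test the scale-free property of a built
    network; degree 0 bins and zero counts are ignored.
    """
    pts = [
        (d, c)
        for d, c in degree_histogram.items()
        if d > 0 and c > 0
    ]
    if len({d for d, _ in pts}) < 2:
        raise UndefinedFitError("need at least 2 distinct non-zero degrees for a power-law fit")
    x = np.log10([d for d, _ in pts])
    y = np.log10([c for _, c in pts])
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope)


def degree_histogram(net: nx.Graph) -> dict[int, int]:
    hist: dict[int, int] = {}
    for _, d in net.degree():
        hist[d] = hist.get(d, 0) + 1
    return hist


def network_exposibility(net: nx.Graph) -> float:
    """Total nodes divided by total connected components.

    Isolated nodes each count as one component, so a fully fragmented network
    scores 1 and a connected network scores its node count.
    """
    if net.number_of_nodes() == 0:
        raise InputError("exposibility is undefined for an empty network")
    return net.number_of_nodes() / nx.number_connected_components(net)


def filter_by_exposibility(
    nets: Mapping[str, nx.Graph], threshold: float = EXPOSIBILITY_MIN
) -> set[str]:
    """Diseases whose network exposibility is >= threshold (inclusive)."""
    if not nets:
        raise InputError("no networks to filter")
    passing = {d for d, g in nets.items() if network_exposibility(g) >= threshold}
    if not passing:
        logger.warning("no network reached exposibility >= %g", threshold)
    return passing


def core_network(nets: list[nx.Graph]) -> nx.Graph:
    """Edges present in every input network; weight is the minimum across inputs.

    Nodes of the core are the endpoints of surviving edges, so the operation
    is order-independent and the result is a subnetwork of every input.
    """
    if len(nets) < 2:
        raise InputError("core network needs at least 2 input networks")
    edge_sets = [
        {frozenset((u, v)) for u, v in g.edges() if u != v} for g in nets
    ]
    common = reduce(set.intersection, edge_sets)
    core = nx.Graph()
    for pair in common:
        u, v = sorted(pair)
        core.add_edge(u, v, weight=min(g[u][v].get("weight", 1.0) for g in nets))
    return core
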