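"""Disease protein-protein interaction networks from a reference interactome.

The reference is a STRING-style weighted edge list.  A disease PPI network is
the reference subgraph induced on that disease's seed proteins — the union
(optionally intersection) of its co-expressed genes and its differentially
expressed genes — with edge-less proteins dropped.
"""

from __future__ import annotations

import logging
from functools import reduce
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConfigurationError, InputError, ParseError

logger = logging.getLogger(__name__)

#: STRING medium-confidence convention
DEFAULT_SCORE_MIN = 0.4


def load_reference_interactome(path, score_min: float = DEFAULT_SCORE_MIN) -> nx.Graph:
    """Read a three-column (gene_a, gene_b, score) TSV into an undirected graph.

    Self-loop rows are dropped (with a warning count), duplicate unordered
    pairs keep the maximum score, and edges scoring below ``score_min`` are
    discarded.
    """
    if not 0 <= score_min <= 1:
        raise ConfigurationError("score_min must lie in [0, 1]")
    best: dict[frozenset, float] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["gene_a", "gene_b"]:
                continue  # optional header
            if len(parts) != 3:
                raise ParseError(f"expected 3 tab-separated columns, got {len(parts)}", lineno)
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError:
                raise ParseError(f"score {raw!r} is not a number", lineno) from None
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            if score > best.get(key, float("-inf")):
                best[key] = score
    if n_self:
        logger.warning("dropped %d self-loop row(s) from %s", n_self, path)
    graph = nx.Graph()
    for key, score in best.items():
        if score < score_min:
            continue
        a, b = sorted(key)
        graph.add_edge(a, b, weight=score)
    return graph


def build_disease_ppi(
    gcn_nodes: Iterable[str],
    degs: Iterable[str],
    reference: nx.Graph,
    combine: str = "union",
) -> nx.Graph:
    """Reference subgraph induced on the disease's seed proteins.

    The seed set fuses the co-expression network's gene list with the DEGs;
    ``combine`` selects union (default) or intersection.  Proteins with no
    surviving interaction are dropped.
    """
    if reference.number_of_nodes() == 0:
        raise InputError("reference interactome is empty")
    gcn_nodes, degs = set(gcn_nodes), set(degs)
    if combine == "union":
        seed = gcn_nodes | degs
    elif combine == "intersection":
        seed = gcn_nodes & degs
    else:
        raise ConfigurationError(f"combine must be 'union' or 'intersection', got {combine!r}")
    if not seed:
        raise InputError("empty seed set: no co-expressed genes or DEGs supplied")
    sub = reference.subgraph(seed)
    keep = [n for n, d in sub.degree() if d > 0]
    return sub.subgraph(keep).copy()


def annotate_expression_status(
    net: nx.Graph, fdr_by_gene: Mapping[str, float], fdr_max: float = 0.05
) -> None:
    """Tag each node Exp / Not-Exp by its differential-expression FDR."""
    for node in net.nodes:
        fdr = fdr_by_gene.get(node)
        net.nodes[node]["expressed"] = bool(fdr is not None and fdr < fdr_max)


def shared_nodes(nets: list[nx.Graph]) -> set[str]:
    """Proteins present in every input network."""
    if len(nets) < 2:
        raise InputError("need at least 2 networks to intersect")
    return reduce(set.intersection, (set(g.nodes) for g in nets))
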