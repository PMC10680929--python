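"""Publication-filtered drug-gene interactions and the bipartite drug network.

Interaction tables follow the DGIdb-style TSV layout: drug, gene,
interaction_type, pmids (comma-separated publication ids, possibly empty).
Only interactions backed by at least one publication are mapped onto the
high-priority proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ("drug", "gene", "interaction_type", "pmids")


@dataclass
class DrugNetworkSummary:
    n_genes_with_drugs: int
    n_drugs: int
    n_interactions: int


def _pmid_list(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    return [p.strip() for p in str(raw).split(",") if p.strip()]


def filter_published_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Keep rows carrying at least one publication id; row order preserved."""
    keep = table["pmids"].map(lambda raw: bool(_pmid_list(raw)))
    if not keep.any():
        logger.warning("no drug-gene interaction has publication evidence")
    return table[keep].copy()


def build_drug_gene_network(
    hpps: set[str], table: pd.DataFrame
) -> tuple[nx.Graph, DrugNetworkSummary]:
    """Bipartite drug-HPP network plus its summary counts.

    Rows whose gene is not an HPP are dropped.  Duplicate (drug, gene) rows
    collapse to a single edge whose publication list is the union, and drug
    names are deduplicated case-insensitively, so ``n_interactions`` counts
    unique drug-gene pairs.
    """
    net = nx.Graph()
    canonical: dict[str, str] = {}  # lowercase drug -> first-seen spelling
    for row in table.itertuples(index=False):
        gene = row.gene
        if gene not in hpps:
            continue
        drug = canonical.setdefault(str(row.drug).lower(), str(row.drug))
        pmids = set(_pmid_list(row.pmids))
        if net.has_edge(drug, gene):
            merged = set(_pmid_list(net[drug][gene]["pmids"])) | pmids
            net[drug][gene]["pmids"] = ",".join(sorted(merged))
        else:
            net.add_node(drug, bipartite="drug")
            net.add_node(gene, bipartite="gene")
            # pmids kept as a comma-joined string so GraphML export round-trips
            net.add_edge(
                drug,
                gene,
                pmids=",".join(sorted(pmids)),
                interaction_type=row.interaction_type,
            )
    genes = {n for n, d in net.nodes(data=True) if d.get("bipartite") == "gene"}
    drugs = {n for n, d in net.nodes(data=True) if d.get("bipartite") == "drug"}
    summary = DrugNetworkSummary(len(genes), len(drugs), net.number_of_edges())
    return net, summary
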