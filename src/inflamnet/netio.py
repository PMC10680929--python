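"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as a TSV (gene_id + one column per sample) with a
sidecar sample->group TSV; networks as weighted edge-list TSV or GraphML;
gene sets as GMT; knowledge tables as TSV.  Edge weights are written with
17 significant digits so an export/import round trip is exact.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import pandas as pd

from .diffexpr import ExpressionMatrix
from .errors import ConfigurationError, ParseError


def write_expression(mat: ExpressionMatrix, values_path, groups_path) -> None:
    mat.values.to_csv(values_path, sep="\t", float_format="%.10g")
    pd.Series(mat.groups, name="group").rename_axis("sample_id").to_csv(
        groups_path, sep="\t"
    )


def read_expression(values_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].to_dict()
    return ExpressionMatrix(values, groups)


def write_edge_list(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (e[0], e[1])):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.17g}\n")


def read_edge_list(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["node_a", "node_b"]:
                continue
            if len(parts) != 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", lineno)
            try:
                weight = float(parts[2])
            except ValueError:
                raise ParseError(f"weight {parts[2]!r} is not a number", lineno) from None
            graph.add_edge(parts[0], parts[1], weight=weight)
    return graph


def export_network(net: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write a network as edge-list TSV (``tsv``) or GraphML (``graphml``)."""
    if fmt == "tsv":
        write_edge_list(net, path)
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")


def import_network(path, fmt: str = "tsv") -> nx.Graph:
    if fmt == "tsv":
        return read_edge_list(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ConfigurationError(f"unknown network format {fmt!r}")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: tab-separated term, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT rows need term, description, and >= 1 gene", lineno)
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, set[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"pmids": str}, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
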