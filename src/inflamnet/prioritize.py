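"""High-priority protein identification, cross-disease sharing, and enrichment.

A protein is *significant* in a disease when it falls in the top 5% of any of
the four centralities or in the inner layer of the weighted k-shell
decomposition.  A significant protein becomes a *high-priority protein*
(HPP) when the regulator-activity table also calls it significantly
activated or inhibited in that disease: |activation z| > 1 (strict) and
BH-adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .centrality import CENTRALITY_COLUMNS, DEFAULT_TOP_FRACTION, top_fraction
from .errors import ConfigurationError, InputError

Z_MIN = 1.0
P_MAX = 0.05


@dataclass
class Neighborhood:
    """Three-source interaction neighborhood of a focus regulator."""

    focus: str
    tf_targets: set[str]
    ppi_partners: set[str]
    coexpressed: set[str]

    def union(self) -> set[str]:
        return self.tf_targets | self.ppi_partners | self.coexpressed


def significant_proteins(
    cent: pd.DataFrame, fraction: float = DEFAULT_TOP_FRACTION
) -> set[str]:
    """Union of the four top-fraction centrality sets and the inner k-shell layer."""
    missing = [c for c in (*CENTRALITY_COLUMNS, "layer") if c not in cent.columns]
    if missing:
        raise InputError(f"centrality table is missing columns: {missing}")
    selected: set[str] = set(cent.index[cent["layer"] == "inner"])
    for col in CENTRALITY_COLUMNS:
        selected |= top_fraction(cent[col].to_dict(), fraction)
    return selected


def identify_hpps(
    sig: set[str],
    activity: pd.DataFrame,
    disease: str,
    z_min: float = Z_MIN,
    p_max: float = P_MAX,
) -> set[str]:
    """Significant proteins that are also significantly active regulators.

    ``activity`` has columns regulator / disease / activation_z / bh_p; a
    protein absent from the table for the disease is excluded.
    """
    rows = activity[activity["disease"] == disease]
    if rows.empty:
        raise InputError(f"activity table has no rows for disease {disease!r}")
    active = set(
        rows.loc[
            (rows["activation_z"].abs() > z_min) & (rows["bh_p"] < p_max), "regulator"
        ]
    )
    return sig & active


def venn_partition(
    sets: Mapping[str, set[str]],
) -> dict[tuple[str, ...], set[str]]:
    """All 2^k - 1 disjoint membership regions of up to six labelled sets.

    Keys are sorted tuples of the labels a region belongs to; the regions
    partition the union of the inputs (empty regions included).
    """
    labels = sorted(sets)
    if not 2 <= len(labels) <= 6:
        raise ConfigurationError("venn partition supports 2-6 sets")
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions[combo] = set()
    for gene in set().union(*sets.values()):
        signature = tuple(lab for lab in labels if gene in sets[lab])
        regions[signature].add(gene)
    return regions


def hypergeometric_ora(
    study: set[str],
    universe: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set against GMT terms.

    Per term, p is the upper-tail probability of observing at least the seen
    overlap when drawing |study| genes from the universe; BH adjustment runs
    across terms.  Terms are intersected with the universe first and skipped
    if the intersection is empty.
    """
    offenders = study - universe
    if offenders:
        raise InputError(f"study genes outside the universe: {sorted(offenders)[:5]}")
    m = len(universe)
    n_study = len(study)
    rows = []
    for term, genes in gene_sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = len(study & in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(in_universe), n_study))
        rows.append((term, overlap, len(in_universe), p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    if not table.empty:
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table.set_index("term").sort_values("p_value")


def master_regulator_neighborhood(
    focus: str,
    ppi: nx.Graph,
    gcn: nx.Graph,
    tf_targets: pd.DataFrame,
) -> Neighborhood:
    """Targets, PPI partners, and co-expressed genes of a focus regulator.

    The three sets come from the TF-target table, direct PPI neighbors, and
    direct co-expression neighbors; they may overlap each other but never
    contain the focus itself.
    """
    targets = set(tf_targets.loc[tf_targets["tf"] == focus, "target"])
    in_ppi = focus in ppi
    in_gcn = focus in gcn
    if not (targets or in_ppi or in_gcn):
        raise InputError(f"{focus!r} is absent from the TF table, PPI, and GCN")
    partners = set(ppi.neighbors(focus)) if in_ppi else set()
    coexpr = set(gcn.neighbors(focus)) if in_gcn else set()
    return Neighborhood(
        focus=focus,
        tf_targets=targets - {focus},
        ppi_partners=partners - {focus},
        coexpressed=coexpr - {focus},
    )
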