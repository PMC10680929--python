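"""Synthetic multi-disease cohorts, a reference interactome, and knowledge tables.

The generator emulates the study design the pipeline targets: several case/
control skin-biopsy transcriptome cohorts that share some differentially
expressed genes, carry correlated co-expression modules, and map onto a
scale-free protein interactome.  Every planted structure is returned as
ground truth so each downstream stage can be tested offline.

Expression model (log2 scale): control samples draw Normal(baseline,
noise_sd) per gene; case samples of a planted DE gene are shifted by
+/- effect_log2fc with a random sign fixed per gene.  Module correlation is
induced by a shared latent factor per module: a module gene's noise is
sqrt(rho)*factor + sqrt(1-rho)*eps, so the expected pairwise Pearson
correlation equals ``module_cor`` regardless of noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import CASE, CONTROL, ExpressionMatrix
from .errors import ConfigurationError, InputError

#: number of shared DE genes that are also planted as interactome hubs
N_SHARED_HUBS = 5
#: preferential-attachment multiplicity boost for planted hubs
HUB_BOOST = 15
MASTER_BOOST = 30
#: drugs attached to the planted master regulator (mirrors a six-drug target)
N_MASTER_DRUGS = 6


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic multi-disease cohort.

    Defaults describe a four-disease study: 20 case vs 20 control samples per
    disease, 600 genes, a block of DE genes shared by all diseases plus a
    unique block per disease (planted |log2FC| = 2, well above the calling
    threshold of 1), two 30-gene co-expression modules shared across diseases,
    and Gaussian log2-scale noise with sd 0.5 — magnitudes typical of the
    moderately sized bulk case/control series the pipeline is aimed at.
    """

    n_diseases: int = 4
    n_genes: int = 600
    n_samples_per_group: int = 20
    n_shared_de: int = 40
    n_unique_de_per_disease: int = 20
    effect_log2fc: float = 2.0
    n_modules: int = 2
    module_size: int = 30
    module_cor: float = 0.8
    noise_sd: float = 0.5
    baseline: float = 8.0
    seed: int = 0
    small_disease: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_diseases", "n_genes", "n_samples_per_group", "module_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("n_shared_de", "n_unique_de_per_disease", "n_modules"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.effect_log2fc < 0 or self.noise_sd < 0:
            raise ConfigurationError("effect_log2fc and noise_sd must be non-negative")
        if not 0 <= self.module_cor <= 1:
            raise ConfigurationError("module_cor must lie in [0, 1]")
        planted = (
            self.n_shared_de
            + self.n_diseases * self.n_unique_de_per_disease
            + self.n_modules * self.module_size
        )
        # +1 spare gene hosts the master regulator, which is DE in only a
        # subset of diseases and therefore cannot live in the shared block
        if planted + 1 > self.n_genes:
            raise ConfigurationError(
                "planted genes exceed n_genes: n_shared_de + n_diseases*"
                "n_unique_de_per_disease + n_modules*module_size + 1 = "
                f"{planted + 1} > {self.n_genes}"
            )

    @property
    def diseases(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_diseases)]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    de_genes_per_disease: dict[str, dict[str, float]]  # disease -> gene -> signed lfc
    module_assignments: dict[str, int]  # gene -> module id
    planted_hubs: set[str]
    planted_master_regulator: str
    master_regulator_diseases: list[str] = field(default_factory=list)
    planted_targets: set[str] = field(default_factory=set)

    def de_sets(self) -> dict[str, set[str]]:
        return {d: set(g) for d, g in self.de_genes_per_disease.items()}

    def planted_module_edges(self) -> set[frozenset[str]]:
        """All within-module gene pairs (the planted co-expression edges)."""
        by_module: dict[int, list[str]] = {}
        for g, m in self.module_assignments.items():
            by_module.setdefault(m, []).append(g)
        edges: set[frozenset[str]] = set()
        for genes in by_module.values():
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    edges.add(frozenset((a, b)))
        return edges


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Simulate one expression matrix per disease plus the planted truth.

    Deterministic: identical config (including seed) reproduces the outputs
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    diseases = config.diseases
    if config.small_disease is not None and config.small_disease not in diseases:
        raise ConfigurationError(
            f"small_disease {config.small_disease!r} is not one of {diseases}"
        )

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor : cursor + k]
        cursor += k
        return block

    shared = take(config.n_shared_de)
    unique = {d: take(config.n_unique_de_per_disease) for d in diseases}
    modules = {m: take(config.module_size) for m in range(config.n_modules)}
    master = take(1)[0]

    # a "small" disease emulates a cohort with too few DEGs to contribute to
    # the cross-disease intersection: it keeps a fifth of its unique block
    # and none of the shared block
    if config.small_disease is not None:
        d = config.small_disease
        unique[d] = unique[d][: max(1, len(unique[d]) // 5)]

    signs = {g: float(rng.choice((-1.0, 1.0))) for g in shared}
    for d in diseases:
        signs.update({g: float(rng.choice((-1.0, 1.0))) for g in unique[d]})
    signs[master] = 1.0  # the master regulator is planted as activated

    master_diseases = diseases[: min(3, config.n_diseases)]
    de: dict[str, dict[str, float]] = {}
    for d in diseases:
        table = {} if d == config.small_disease else {g: signs[g] * config.effect_log2fc for g in shared}
        table.update({g: signs[g] * config.effect_log2fc for g in unique[d]})
        if d in master_diseases:
            table[master] = config.effect_log2fc
        de[d] = table

    module_of = {g: m for m, block in modules.items() for g in block}
    hubs = {master} | set(shared[:N_SHARED_HUBS])
    truth = GroundTruth(
        de_genes_per_disease=de,
        module_assignments=module_of,
        planted_hubs=hubs,
        planted_master_regulator=master,
        master_regulator_diseases=master_diseases,
        planted_targets=set(),
    )

    n = config.n_samples_per_group
    sqrt_rho = np.sqrt(config.module_cor)
    sqrt_res = np.sqrt(1.0 - config.module_cor)
    cohorts: dict[str, ExpressionMatrix] = {}
    for d in diseases:
        eps = rng.standard_normal((config.n_genes, 2 * n))
        # shared latent factor per module induces pairwise correlation rho
        for m, block in modules.items():
            factor = rng.standard_normal(2 * n)
            rows = [genes.index(g) for g in block]
            eps[rows] = sqrt_rho * factor + sqrt_res * eps[rows]
        values = config.baseline + config.noise_sd * eps
        for g, effect in de[d].items():
            values[genes.index(g), :n] += effect
        samples = [f"{d}_case_{i + 1}" for i in range(n)] + [
            f"{d}_ctrl_{i + 1}" for i in range(n)
        ]
        groups = {s: (CASE if i < n else CONTROL) for i, s in enumerate(samples)}
        cohorts[d] = ExpressionMatrix(
            pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
            groups,
        )
    return cohorts, truth


def generate_reference_interactome(
    gene_ids: list[str],
    attach_edges: int = 2,
    seed: int = 0,
    hubs: set[str] | None = None,
    master: str | None = None,
) -> nx.Graph:
    """Preferential-attachment interactome over all gene ids.

    Grows a Barabasi-Albert-style graph: nodes arrive one at a time and
    attach ``attach_edges`` edges to existing nodes sampled proportionally to
    degree.  Planted hubs (and, more strongly, the master regulator) are
    seeded early and over-weighted in the attachment pool, so they end up
    high-degree.  Edge confidence scores are uniform on (0, 1].  The degree
    distribution follows a power law, as protein interactomes do.
    """
    n = len(gene_ids)
    if attach_edges < 1:
        raise ConfigurationError("attach_edges must be a positive integer")
    if attach_edges >= n:
        raise ConfigurationError(
            f"attach_edges ({attach_edges}) must be smaller than the number of genes ({n})"
        )
    if len(set(gene_ids)) != n:
        raise InputError("gene_ids must be unique")
    hubs = set(hubs or ())

    rng = np.random.default_rng(seed)
    # hubs first so they are present from the start of the growth process
    order = sorted(hubs & set(gene_ids)) + [g for g in gene_ids if g not in hubs]
    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)

    pool: list[str] = []  # node repeated once per unit of attachment weight

    def boost(g: str) -> int:
        if g == master:
            return MASTER_BOOST
        return HUB_BOOST if g in hubs else 1

    m0 = attach_edges + 1
    for i, g in enumerate(order[:m0]):
        for h in order[:i]:
            graph.add_edge(g, h, weight=1.0 - rng.random())
            pool.extend((g, h))
        pool.extend([g] * boost(g))

    for g in order[m0:]:
        targets: set[str] = set()
        while len(targets) < attach_edges:
            targets.add(pool[rng.integers(len(pool))])
        # sorted iteration keeps the build independent of hash randomization
        for h in sorted(targets):
            graph.add_edge(g, h, weight=1.0 - rng.random())
            pool.append(h)
        pool.extend([g] * (attach_edges + boost(g) - 1))
    return graph


def generate_knowledge_tables(
    truth: GroundTruth, seed: int = 0, n_decoys: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Regulator-activity, drug-gene, and TF-target tables from planted truth.

    The activity table gives every planted hub |z| > 1 and BH p < 0.05 in each
    disease where it is DE (sign matching the planted direction) and gives
    decoy regulators sub-threshold activity, so the high-priority-protein
    filter has both true and false candidates.  The drug table carries rows
    with and without publication ids to exercise the publication filter; the
    planted master regulator receives six published drugs.  The TF-target
    table lists the master regulator's planted targets.
    """
    if not truth.de_genes_per_disease:
        raise InputError("ground truth has no diseases")
    rng = np.random.default_rng(seed)
    diseases = list(truth.de_genes_per_disease)
    master = truth.planted_master_regulator

    activity_rows = []
    for g in sorted(truth.planted_hubs):
        for d in diseases:
            effect = truth.de_genes_per_disease[d].get(g)
            if effect is None:
                continue
            z = np.sign(effect) * (1.5 + rng.random())
            activity_rows.append((g, d, float(z), float(0.001 + 0.02 * rng.random())))
    all_genes = sorted(truth.module_assignments) or sorted(
        set().union(*(set(t) for t in truth.de_genes_per_disease.values()))
    )
    decoys = [g for g in all_genes if g not in truth.planted_hubs][:n_decoys]
    for g in decoys:
        for d in diseases:
            activity_rows.append(
                (g, d, float(rng.uniform(-0.8, 0.8)), float(rng.uniform(0.2, 0.9)))
            )
    activity = pd.DataFrame(
        activity_rows, columns=["regulator", "disease", "activation_z", "bh_p"]
    )

    drug_rows = []
    for k in range(N_MASTER_DRUGS):
        drug_rows.append(
            (f"drug_M{k + 1}", master, "inhibitor", str(10_000_000 + int(rng.integers(1_000_000))))
        )
    for g in sorted(truth.planted_hubs - {master}):
        for k in range(int(rng.integers(1, 4))):
            drug_rows.append(
                (f"drug_{g}_{k + 1}", g, "modulator", str(20_000_000 + int(rng.integers(1_000_000))))
            )
    # unpublished rows: real databases carry evidence-free interactions too
    for k, g in enumerate(sorted(truth.planted_hubs)[:3]):
        drug_rows.append((f"drug_unpub_{k + 1}", g, "unknown", ""))
    drugs = pd.DataFrame(drug_rows, columns=["drug", "gene", "interaction_type", "pmids"])

    candidates = [
        g
        for d in truth.master_regulator_diseases or diseases
        for g in sorted(truth.de_genes_per_disease[d])
        if g != master
    ]
    targets = sorted(set(candidates))[:10]
    truth.planted_targets = set(targets)
    tf = pd.DataFrame({"tf": master, "target": targets})
    return activity, drugs, tf


def generate_gene_sets(truth: GroundTruth, universe: list[str]) -> dict[str, set[str]]:
    """Small GMT-style collection built from the planted truth.

    One term per planted module plus a term for the genes DE in every disease;
    used as the annotation source for over-representation analysis in fully
    synthetic runs.
    """
    by_module: dict[int, set[str]] = {}
    for g, m in truth.module_assignments.items():
        by_module.setdefault(m, set()).add(g)
    sets = {f"planted_module_{m}": genes for m, genes in sorted(by_module.items())}
    de_sets = truth.de_sets()
    if de_sets:
        common = set.intersection(*de_sets.values())
        if common:
            sets["planted_shared_de"] = common
    uni = set(universe)
    return {term: genes & uni for term, genes in sets.items() if genes & uni}
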