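"""End-to-end orchestration: cohort -> DE -> GCN -> PPI -> centralities -> HPPs -> drugs.

A :class:`PipelineConfig` carries every threshold with the study defaults
(|log2FC| >= 1, FDR < 0.05, exposibility >= 10, top 5% centralities, |z| > 1),
so a bare run reproduces the reference analysis conditions.  Inputs are
either file paths per disease or a synthetic cohort design; outputs are
TSV/GraphML artifacts plus a machine-readable JSON summary.  The whole run
is deterministic in (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import coexpression, diffexpr, drugmap, interactome, netio, prioritize, simulate
from .centrality import DEFAULT_ALPHA, DEFAULT_INNER_FRACTION, centrality_table
from .errors import ConfigurationError, InflamnetError, UndefinedFitError
from .simulate import CohortConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, inputs, and output location for one pipeline run.

    With no ``expression_paths`` the cohort is simulated from ``cohort``;
    likewise the reference interactome and knowledge tables are generated
    from the planted ground truth unless paths are given.
    """

    # inputs: either file paths per disease or a synthetic design
    expression_paths: dict[str, tuple[str, str]] = field(default_factory=dict)
    reference_path: str | None = None
    activity_path: str | None = None
    drug_path: str | None = None
    tf_path: str | None = None
    gmt_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)

    # thresholds (defaults are the reference analysis conditions)
    lfc_min: float = diffexpr.LFC_MIN
    fdr_max: float = diffexpr.FDR_MAX
    soft_power: int | None = None  # None -> scale-free auto-selection
    candidate_powers: tuple[int, ...] = coexpression.DEFAULT_POWERS
    target_r2: float = 0.8
    weight_cutoff: float = coexpression.DEFAULT_WEIGHT_CUTOFF
    score_min: float = interactome.DEFAULT_SCORE_MIN
    exposibility_min: float = coexpression.EXPOSIBILITY_MIN
    top_fraction: float = 0.05
    z_min: float = prioritize.Z_MIN
    p_max: float = prioritize.P_MAX
    alpha: float = DEFAULT_ALPHA
    inner_fraction: float = DEFAULT_INNER_FRACTION
    attach_edges: int = 2
    combine_seed: str = "union"
    exclude_from_shared: tuple[str, ...] = ()
    focus_gene: str | None = None

    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "expression_paths" in raw:
            raw["expression_paths"] = {
                d: tuple(v) for d, v in raw["expression_paths"].items()
            }
        return cls(cohort=cohort, **raw)


@contextmanager
def _stage(name: str, **params):
    logger.info("stage %s: %s", name, params)
    try:
        yield
    except InflamnetError as exc:
        raise InflamnetError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run summary.

    Stage order: differential expression -> shared DEGs -> co-expression
    networks -> exposibility filter -> disease PPIs -> centralities and
    weighted k-shell -> significant proteins -> HPPs -> Venn sharing ->
    over-representation -> master-regulator neighborhood -> drug network.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            "lfc_min": config.lfc_min,
            "fdr_max": config.fdr_max,
            "weight_cutoff": config.weight_cutoff,
            "score_min": config.score_min,
            "exposibility_min": config.exposibility_min,
            "top_fraction": config.top_fraction,
            "z_min": config.z_min,
            "p_max": config.p_max,
            "alpha": config.alpha,
            "inner_fraction": config.inner_fraction,
        },
        "diseases": {},
    }

    truth = None
    with _stage("cohort", seed=config.seed):
        if config.expression_paths:
            cohorts = {
                d: netio.read_expression(v, g)
                for d, (v, g) in config.expression_paths.items()
            }
        else:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohorts, truth = simulate.generate_cohort(cohort_cfg)
    diseases = sorted(cohorts)
    for d in diseases:
        summary["diseases"][d] = {}

    deg_tables, deg_sets = {}, {}
    with _stage("differential_expression", lfc_min=config.lfc_min, fdr_max=config.fdr_max):
        for d in diseases:
            table = diffexpr.differential_expression(
                cohorts[d], config.lfc_min, config.fdr_max
            )
            up, down = diffexpr.threshold_degs(table, config.lfc_min, config.fdr_max)
            deg_tables[d] = table
            deg_sets[d] = up | down
            summary["diseases"][d].update(n_up=len(up), n_down=len(down), n_degs=len(up | down))
            if outdir:
                diffexpr.write_deg_table(table, outdir / f"{d}_degs.tsv")

    with _stage("shared_degs", exclude=config.exclude_from_shared):
        shared = diffexpr.shared_degs(deg_sets, exclude=config.exclude_from_shared)
        summary["shared_degs"] = sorted(shared)
        summary["n_shared_degs"] = len(shared)

    gcns, reported = {}, {}
    with _stage("coexpression", power=config.soft_power, cutoff=config.weight_cutoff):
        for d in diseases:
            if config.soft_power is None:
                chosen = coexpression.select_soft_power(
                    cohorts[d], config.candidate_powers, config.target_r2
                )
                power, fits = chosen.power, chosen.fit_r2_by_power
            else:
                power, fits = config.soft_power, {}
            gcn = coexpression.build_gcn(cohorts[d], power, config.weight_cutoff)
            rep = coexpression.edge_incident_subgraph(gcn)
            expo = (
                coexpression.network_exposibility(rep) if rep.number_of_nodes() else 0.0
            )
            try:
                r2, slope = coexpression.powerlaw_fit(coexpression.degree_histogram(rep))
            except UndefinedFitError:
                r2, slope = float("nan"), float("nan")
            gcns[d], reported[d] = gcn, rep
            summary["diseases"][d].update(
                soft_power=power,
                fit_r2_by_power={int(k): float(v) for k, v in fits.items()},
                gcn_nodes=rep.number_of_nodes(),
                gcn_edges=rep.number_of_edges(),
                exposibility=expo,
                gcn_powerlaw_r2=r2,
            )
            if outdir:
                netio.export_network(rep, outdir / f"{d}_gcn.tsv")

    with _stage("exposibility_filter", threshold=config.exposibility_min):
        passing = sorted(
            coexpression.filter_by_exposibility(
                {d: g for d, g in reported.items() if g.number_of_nodes()},
                config.exposibility_min,
            )
        )
        for d in diseases:
            summary["diseases"][d]["passes_exposibility"] = d in passing
        summary["diseases_passing_exposibility"] = passing

    if len(passing) >= 2:
        with _stage("core_network"):
            core = coexpression.core_network([reported[d] for d in passing])
            summary["core_gcn"] = {
                "diseases": passing,
                "nodes": core.number_of_nodes(),
                "edges": core.number_of_edges(),
            }
            if outdir:
                netio.export_network(core, outdir / "core_gcn.tsv")

    if not passing:
        summary["notice"] = "no disease passed the exposibility filter; downstream stages skipped"
        if outdir:
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary

    with _stage("reference_interactome", score_min=config.score_min):
        if config.reference_path:
            reference = interactome.load_reference_interactome(
                config.reference_path, config.score_min
            )
        else:
            all_genes = sorted(set().union(*(c.gene_ids for c in cohorts.values())))
            reference = simulate.generate_reference_interactome(
                all_genes,
                attach_edges=config.attach_edges,
                seed=config.seed + 1,
                hubs=truth.planted_hubs if truth else None,
                master=truth.planted_master_regulator if truth else None,
            )
            reference = nx.Graph(
                (u, v, d) for u, v, d in reference.edges(data=True)
                if d["weight"] >= config.score_min
            )
        summary["reference_interactome"] = {
            "nodes": reference.number_of_nodes(),
            "edges": reference.number_of_edges(),
        }

    with _stage("knowledge_tables"):
        activity = drugs_raw = tf_table = None
        if truth is not None:
            activity, drugs_raw, tf_table = simulate.generate_knowledge_tables(
                truth, seed=config.seed + 2
            )
        if config.activity_path:
            activity = netio.read_table(
                config.activity_path, ("regulator", "disease", "activation_z", "bh_p")
            )
        if config.drug_path:
            drugs_raw = netio.read_table(config.drug_path, drugmap.COLUMNS)
        if config.tf_path:
            tf_table = netio.read_table(config.tf_path, ("tf", "target"))
        if activity is None:
            raise ConfigurationError(
                "regulator-activity table required: set activity_path for file-based runs"
            )
        if drugs_raw is None:
            drugs_raw = pd.DataFrame(columns=list(drugmap.COLUMNS))
        if tf_table is None:
            tf_table = pd.DataFrame(columns=["tf", "target"])

    ppis, cent_tables, sig_sets, hpp_sets = {}, {}, {}, {}
    with _stage("interactome", combine=config.combine_seed):
        for d in passing:
            ppi = interactome.build_disease_ppi(
                reported[d].nodes, deg_sets[d], reference, combine=config.combine_seed
            )
            interactome.annotate_expression_status(
                ppi, deg_tables[d]["fdr"].to_dict(), config.fdr_max
            )
            ppis[d] = ppi
            summary["diseases"][d].update(
                ppi_nodes=ppi.number_of_nodes(), ppi_edges=ppi.number_of_edges()
            )
            if outdir:
                netio.export_network(ppi, outdir / f"{d}_ppi.graphml", fmt="graphml")

    with _stage("centralities", alpha=config.alpha, inner_fraction=config.inner_fraction):
        for d in passing:
            table = centrality_table(ppis[d], config.alpha, config.inner_fraction)
            cent_tables[d] = table
            if outdir:
                table.to_csv(outdir / f"{d}_centrality.tsv", sep="\t", float_format="%.8g")

    with _stage("significant_proteins", fraction=config.top_fraction):
        for d in passing:
            sig = prioritize.significant_proteins(cent_tables[d], config.top_fraction)
            sig_sets[d] = sig
            summary["diseases"][d]["n_significant_proteins"] = len(sig)

    with _stage("hpps", z_min=config.z_min, p_max=config.p_max):
        for d in passing:
            hpps = prioritize.identify_hpps(
                sig_sets[d], activity, d, config.z_min, config.p_max
            )
            assert hpps <= sig_sets[d] <= set(ppis[d].nodes)
            hpp_sets[d] = hpps
            summary["diseases"][d]["hpps"] = sorted(hpps)
            summary["diseases"][d]["n_hpps"] = len(hpps)

    if len(passing) >= 2:
        with _stage("sharing"):
            summary["shared_ppi_proteins"] = sorted(
                interactome.shared_nodes([ppis[d] for d in passing])
            )
            regions = prioritize.venn_partition({d: sig_sets[d] for d in passing})
            summary["significant_protein_venn"] = {
                "+".join(labels): sorted(genes)
                for labels, genes in regions.items()
                if genes
            }

    universe = set().union(*(set(ppis[d].nodes) for d in passing))
    study = set().union(*(hpp_sets[d] for d in passing))
    with _stage("ora"):
        if config.gmt_path:
            gene_sets = netio.read_gmt(config.gmt_path)
        elif truth is not None:
            gene_sets = simulate.generate_gene_sets(truth, sorted(universe))
        else:
            gene_sets = {}
        if gene_sets and study:
            ora = prioritize.hypergeometric_ora(study, universe, gene_sets)
            summary["ora"] = {
                term: {"overlap": int(r.overlap), "p_value": float(r.p_value), "fdr": float(r.fdr)}
                for term, r in ora.iterrows()
            }
            if outdir:
                ora.to_csv(outdir / "ora.tsv", sep="\t", float_format="%.6g")

    focus = config.focus_gene or (truth.planted_master_regulator if truth else None)
    if focus is not None:
        with _stage("neighborhood", focus=focus):
            host = next(
                (d for d in passing if focus in ppis[d] or focus in reported[d]), None
            )
            if host is not None:
                hood = prioritize.master_regulator_neighborhood(
                    focus, ppis[host], reported[host], tf_table
                )
                summary["master_regulator"] = {
                    "focus": focus,
                    "disease": host,
                    "n_tf_targets": len(hood.tf_targets),
                    "n_ppi_partners": len(hood.ppi_partners),
                    "n_coexpressed": len(hood.coexpressed),
                }
            else:
                summary["master_regulator"] = {"focus": focus, "disease": None}

    with _stage("drug_network"):
        published = drugmap.filter_published_interactions(drugs_raw)
        drug_net, drug_summary = drugmap.build_drug_gene_network(study, published)
        summary["drug_network"] = dataclasses.asdict(drug_summary)
        if outdir:
            netio.export_network(drug_net, outdir / "drug_network.graphml", fmt="graphml")

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
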