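# inflamnet

Network-based prioritization of shared regulator proteins across multiple
case/control transcriptome cohorts.

Chronic inflammatory skin diseases — psoriasis, atopic dermatitis,
hidradenitis suppurativa, rosacea, and relatives — overlap heavily in their
immune programs, yet effective targeted therapy exists for only some of
them. `inflamnet` implements an integrative framework for finding the
proteins most likely to sit at the center of that shared biology: it builds
a weighted gene co-expression network (GCN) per disease, filters unreliable
networks, projects the surviving gene sets onto a reference protein–protein
interactome, scores every protein with five network measures, and keeps the
proteins that are *both* network-central and independently called active
regulators. Those **high-priority proteins (HPPs)** are then mapped to
publication-backed drug–gene interactions to surface repurposing candidates.

## Method in brief

Per disease cohort (genes × samples, log2 scale):

1. **DEGs** — Welch t-test per gene, BH correction; called at
   |log2FC| ≥ 1 and FDR < 0.05.
2. **GCN** — unsigned WGCNA-style soft thresholding: a_ij = |cor(x_i, x_j)|^β,
   edges kept at a_ij ≥ cutoff; β auto-selected by the scale-free topology
   criterion or fixed.
3. **Exposibility filter** — exposibility = N/C (nodes over connected
   components); diseases with exposibility ≥ 10 continue.
4. **Disease PPI** — reference-interactome subgraph induced on
   GCN genes ∪ DEGs (STRING-style edge list, score ≥ 0.4).
5. **Centralities** — degree, betweenness (edge length 1/w), eigenvector
   (max-normalized per component), information centrality
   (n_c / Σ_j r_eff(i,j)), and weighted k-shell decomposition with
   generalized degree k' = round(k^α s^(1−α)), α = 0.5.
6. **Significant proteins** — top 5% by any centrality ∪ inner k-shell layer.
7. **HPPs** — significant proteins with regulator activity |z| > 1 and
   BH p < 0.05 in that disease.
8. **Sharing / enrichment / drugs** — Venn partition across diseases,
   hypergeometric over-representation against GMT gene sets, master-regulator
   neighborhoods (TF targets + PPI partners + co-expressed genes), and a
   bipartite drug–HPP network restricted to publication-backed interactions.

A synthetic-data module generates multi-disease cohorts with planted shared
and unique DEGs, correlated modules, a preferential-attachment interactome
with planted hubs, and matching knowledge tables, so the entire chain is
testable without external databases. See `docs/methods.md` for the full
model and its assumptions.

## Worked example

Run the full pipeline on the default synthetic four-disease study:

```python
from inflamnet import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1, outdir="run1"))
print(summary["n_shared_degs"])                    # 40
print(summary["diseases_passing_exposibility"])    # ['D1', 'D2', 'D3', 'D4']
print(summary["diseases"]["D1"]["n_hpps"])         # 6
print(summary["diseases"]["D1"]["hpps"])
# ['G0001', 'G0002', 'G0003', 'G0004', 'G0005', 'G0181']
print(summary["master_regulator"])
# {'focus': 'G0181', 'disease': 'D1', 'n_tf_targets': 10,
#  'n_ppi_partners': 28, 'n_coexpressed': 60}
print(summary["drug_network"])
# {'n_genes_with_drugs': 6, 'n_drugs': 17, 'n_interactions': 17}
```

Reading: all four simulated diseases pass the exposibility screen; the 40
planted shared DEGs are recovered exactly; disease D1 yields six HPPs — the
five planted hub genes plus `G0181`, the planted master regulator, which is
DE in D1–D3 only and accordingly appears in the D1+D2+D3 region of the
significant-protein Venn partition (`summary["significant_protein_venn"]`).
Its neighborhood merges 10 TF targets, 28 PPI partners and 60 co-expressed
genes, and the six HPP genes map to 17 published drug interactions. Output
files (DEG tables, GCN/PPI networks as TSV/GraphML, centrality tables,
`summary.json`) land in `run1/`.

The same pipeline is scriptable from the shell:

```sh
inflamnet simulate --seed 1 --outdir sim      # write synthetic inputs as TSV
inflamnet run-all  --seed 1 --outdir run1     # full pipeline, synthetic mode
inflamnet de --expr sim/D1_expr.tsv --groups sim/D1_groups.tsv --out degs.tsv
```

File-based runs accept per-disease expression TSVs, a reference interactome
edge list, regulator-activity / drug–gene / TF-target tables, and GMT gene
sets via `PipelineConfig` or a YAML config (`inflamnet run-all --config
cfg.yaml`).

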