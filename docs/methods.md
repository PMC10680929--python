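# Methods

`inflamnet` prioritizes candidate regulator proteins that are shared across
several case/control transcriptome cohorts — the motivating application is
chronic inflammatory skin diseases, where psoriasis-grade therapies exist for
one disease but related conditions lack targets — by chaining differential
expression, co-expression networks, interactome extraction, and a
five-measure network-centrality suite, then cross-referencing against
regulator-activity calls and drug–gene interaction evidence.

## Pipeline model

For each disease cohort (genes × samples, log2 scale, case/control labels):

1. **Differential expression.** Per-gene Welch two-sample t-test on the log2
   values; Benjamini–Hochberg adjustment across all genes of the cohort. A
   differentially expressed gene (DEG) satisfies |log2FC| ≥ 1 (inclusive)
   and FDR < 0.05 (strict). log2FC is case mean − control mean; the sign
   convention is case-over-control and is documented rather than assumed.
   Degenerate genes: constant across all samples → p = 1; zero variance in
   both groups with unequal means → p = 0. The Welch test is used for both
   sequencing-style and array-style inputs; count-model dispersion
   estimation (DESeq2/edgeR-style) is deliberately out of scope — on
   log-scale Gaussian data the Welch test is the transparent choice, and the
   thresholds are what carry the biology here.
2. **Co-expression network (GCN).** WGCNA-style unsigned soft thresholding:
   adjacency a_ij = |pearson(x_i, x_j)|^β, edge kept when a_ij ≥
   weight_cutoff (default 0.1). β is either fixed in config or auto-selected
   as the smallest candidate in 1–12 whose connectivity distribution fits a
   power law with r² ≥ 0.8 (argmax fallback with a warning). Adjacency — not
   topological overlap — defines edge weights, since edge counts are the
   reported quantity downstream. Constant genes are excluded before
   correlation with a logged count. The *reported* network is the
   edge-incident subgraph; isolates are retained in the raw object but not
   in reported counts.
3. **Exposibility filter.** Network exposibility = nodes / connected
   components (isolates count as components). Diseases whose reported GCN
   has exposibility ≥ 10 (inclusive) continue; the rest are considered too
   fragmented for interactome analysis. Exposibility is computed on the
   reported (edge-incident) subgraph — with isolates in the denominator the
   score would sit near 1 for every network and the filter would be vacuous.
4. **Scale-free checks.** Degree histograms are fit by OLS of log10(count)
   on log10(degree) over raw non-zero bins; a network is called scale-free
   when r² ≥ 0.5. Raw bins (no log-binning) match the r²-of-a-line criterion
   applied downstream.
5. **Disease PPI.** The seed set is the union (configurable: intersection)
   of the reported GCN's genes and the DEGs; the disease interactome is the
   reference-interactome subgraph induced on the seed, minus edge-less
   proteins. Reference edges below score_min (default 0.4, the STRING
   medium-confidence convention) are dropped at load time; duplicate pairs
   keep the maximum score. Each PPI node is annotated Exp/Not-Exp by its DE
   FDR (< 0.05).
6. **Centralities.** Degree (unweighted partner count), betweenness
   (unnormalized Brandes with edge length 1/weight so stronger interactions
   are shorter), eigenvector (principal eigenvector of the weighted
   adjacency via dense symmetric eigendecomposition, max-normalized to 1 per
   connected component; "eigenvalue centrality" in the applied literature),
   and information centrality (current-flow form: n_c / Σ_j r_eff(i,j) with
   conductance = edge weight, computed from the Laplacian pseudo-inverse per
   component; singletons score 0, cross-component pairs are excluded rather
   than set to infinite resistance).
7. **Weighted k-shell.** Generalized degree k'_i = round(k_i^α ·
   s_i^(1−α)) with α = 0.5 (configurable in [0, 1]), k degree, s weighted
   strength. Iterative pruning: remove every node with current k' ≤ the
   shell counter (cascading, recomputing k' after removals), assign the
   counter as shell index, increment. With uniform weights this reduces
   exactly to the classical k-core decomposition. The **inner layer** is the
   top quarter of the shell-index *range* (shell ≥ s_max −
   inner_fraction·(s_max − s_min), inner_fraction default 0.25; if all
   shells coincide, everyone is inner). The exact weighting and layer
   boundary of the cited k-shell variants differ between publications, so
   both α and inner_fraction are exposed rather than hard-coded.
8. **Significant proteins and HPPs.** Significant proteins = union of the
   top-5% sets of the four centralities (top set size ceil(0.05·N), ties at
   the cut broken lexicographically for determinism) and the inner k-shell
   layer. A significant protein is a **high-priority protein (HPP)** when
   the regulator-activity table also calls it active in that disease:
   |activation z| > 1 (strict) and BH p < 0.05. Activity is an *input*
   table: upstream-regulator inference engines are proprietary, so their
   output schema (z, BH p per regulator per disease) is consumed instead;
   the synthetic generator produces it from planted truth.
9. **Sharing, enrichment, neighborhoods, drugs.** Venn partition of the
   per-disease significant-protein sets (2–6 sets, all 2^k − 1 disjoint
   regions); hypergeometric over-representation of the HPP union against
   GMT gene sets with the PPI node union as the default background (the
   original meta-enrichment background being unstated, the network universe
   is the defensible default); the master-regulator neighborhood merges
   TF targets, direct PPI partners, and direct GCN neighbors of a focus
   gene; drug–gene interactions without publication ids are discarded
   before the bipartite drug–HPP network is built (duplicate drug–gene
   pairs collapse to one edge, publication lists unioned, drug names
   deduplicated case-insensitively).

All stages are deterministic in (config, seed); every threshold is logged
per stage.

## Synthetic cohorts

`simulate.generate_cohort` emulates the study design: `n_diseases` cohorts
(default 4, labelled D1…Dk) of 20 case + 20 control samples over 600 genes.
Control values are Normal(baseline = 8, noise_sd = 0.5) on the log2 scale;
planted DE genes add ±effect_log2fc (default 2, a strong but realistic
effect that a 20-vs-20 cohort detects reliably at the |log2FC| ≥ 1 cut) to
case samples with a per-gene random sign. A shared DE block (40 genes)
is DE in every disease, a unique block (20) per disease, and two 30-gene
modules carry a shared latent factor so that within-module Pearson
correlation is module_cor (default 0.8) in expectation, independent of
noise_sd. One spare gene is the planted master regulator: DE (activated) in
the first min(3, k) diseases only, over-weighted in the preferential-
attachment reference interactome, given supra-threshold activity rows, six
published drugs, and ten TF targets. One disease may be flagged "small"
(a fifth of its unique block, no shared block) to emulate a cohort excluded
from commonality analysis for lack of DEGs.

What the generator does *not* emulate: negative-binomial count noise,
library-size effects, array normalization artifacts, correlated
case/control confounders, or biologically structured interactomes. Passing
tests therefore demonstrate that the chain recovers planted structure under
Gaussian log-scale noise, not that any specific real cohort would yield the
same gene lists.

A side effect worth knowing: planted DE genes are mutually correlated
across a case/control cohort (the group shift is shared signal), so they
form a dense co-expression clique. That is faithful to real disease
cohorts, but it means "planted co-expression edges" equal within-module
pairs only in designs with the DE blocks switched off — which is how the
module-recovery experiment is configured.

## Numerical choices

- Correlations: `numpy.corrcoef`; soft-power connectivity fits use ten
  equal-width bins of k and OLS on log10 scale.
- BH adjustment: `statsmodels` step-up (verified against a direct
  implementation of the step-up rule).
- Betweenness: exact Brandes (networkx), no sampling; graphs here are 10²–10⁴
  nodes.
- Eigenvector: `numpy.linalg.eigh` per component; the Perron vector's entries
  are taken in absolute value before max-normalization.
- Information: `numpy.linalg.pinv` (hermitian) of the component Laplacian;
  r_eff(i,j) = L⁺_ii + L⁺_jj − 2L⁺_ij.
- Generalized degree uses Python `round` (banker's rounding at .5).
- Mann–Whitney: exact null enumeration when pooled n ≤ 12 and tie-free,
  tie-corrected normal approximation otherwise; two identical constant
  samples return p = 1 by convention.
- Hypergeometric p: `scipy.stats.hypergeom.sf(overlap − 1, …)`.
- Edge weights are serialized with 17 significant digits so TSV/GraphML
  round trips are exact to 1e-12.

## Problem sizes

Default study conditions (600 genes, 4 diseases, 20/group) run the full
pipeline in well under a second, so repeated-seed experiments (recovery
rates, null calibrations at 1000 genes × 50 seeds, 2000-node interactome
fits) are the package's standard verification scale; larger cohorts scale
primarily with the O(n²) correlation step and exact betweenness.

## Known limitations

- The exposibility statistic is sensitive to the weight cutoff; it is a
  coarse reliability screen, not a topology test.
- Auto soft-power selection on strongly clique-structured synthetic data
  often falls back to the argmax power (flagged in the report); fixing the
  power in config is recommended for controlled experiments.
- The five-measure significant-protein rule inherits the arbitrariness of
  the 5% cut and the inner-layer quartile; both are exposed in config.
- ORA assumes the study set is drawn from the declared universe; using a
  different background changes p-values materially.
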