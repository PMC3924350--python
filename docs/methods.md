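# Methods

`mirweave` implements an integrative analysis of paired miRNA and mRNA
expression profiles from a two-group design (ethanol-treated vs control
mouse frontal cortex), together with a synthetic-data generator that
reproduces the statistical structure the analysis assumes. This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Differential expression

Input matrices are log2-scale intensities. mRNA arrays are quantile
normalized (every column is forced onto the shared rank-wise mean
distribution); miRNA arrays are scale normalized (column medians aligned,
median absolute deviations equalized to their geometric mean), mirroring
the platform-appropriate choices for bead arrays and spotted LNA arrays.
A variance-stabilizing transform is not reimplemented: all downstream
statistics depend only on a normalized log-scale matrix, so log2 input is
the contract. Within-array replicate spots are collapsed by their mean —
an estimand-preserving simplification of a replicate-correlation model,
which would add an unidentifiable nuisance parameter at this scale.

The test statistic is the empirical-Bayes moderated t. Per feature g with
pooled two-group variance s²_g on d_g = n₁ + n₂ − 2 degrees of freedom,
the prior s²_g ~ s₀² · F(d_g, d₀) is fitted by moment matching on
log s²_g: the excess variance of log s²_g over trigamma(d_g/2) identifies
trigamma(d₀/2), inverted by Newton iteration; the mean identifies s₀².
Posterior variances s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g) give
t = logFC / (s_post·√(1/n₁+1/n₂)) on d₀ + d_g degrees of freedom
(normal when d₀ = ∞; when observed spread is at or below the sampling
floor the prior is a point mass). Two-sided p-values are adjusted by
Benjamini–Hochberg step-up (via `statsmodels`); differential expression
is called at adj-p strictly below the threshold (default FDR < 0.10 for
miRNAs, < 0.01 for genes, matching the "FDR < 10%"/"FDR < 1%" convention).

## Interaction universe

The miRNA→mRNA universe is a composite of validated interactions plus
predictions supported by at least `min_tools` (default 4) of 11 target
prediction programs. Duplicates are collapsed with validated status taking
precedence while preserving the supporting-tool count. Gene symbols are
compared case-insensitively (human symbols are upper-case, mouse symbols
title-case) with first-seen casing preserved in output. Validated edges
confer membership only; they carry no extra weight in any statistic.

Cross-species miRNA comparison converts species-specific IDs to family
IDs via an explicit family map; a name-normalization fallback (strip
`mmu-`/`hsa-`/`rno-` prefixes and `-3p`/`-5p` arm suffixes, lower-case)
is available for lists published with bare family-style names. The two
conventions can disagree (e.g. `miR-152` as a name vs `mir-148` as its
family), so both routes are exposed and neither is silently substituted
for the other. Gene symbols are converted between taxa through homology
groups (Homologene column layout); every target-taxon member of the
source group is returned, and unmapped symbols are reported, never
dropped.

## Targeting networks and over-targeting

The positively correlated network joins upregulated miRNAs to their
upregulated targets; the negatively correlated network joins upregulated
miRNAs to downregulated targets. Only nodes with degree ≥ 1 are network
members, matching the convention of network viewers in which isolated
candidates are not drawn; interconnectedness is the mean degree
2|E|/|V| over those nodes.

Over-targeting of a miRNA is an upper-tail hypergeometric test: the
population is the expressed genes that appear as a target of at least one
universe miRNA (genes outside the universe can never be drawn as
targets), successes are the DE genes in that population, and the draws
are the miRNA's expressed targets. The symmetric per-mRNA test swaps the
roles (population = expressed universe miRNAs, draws = miRNAs targeting
the gene, restricted to genes targeted by more than one miRNA). One
shared hypergeometric kernel backs these tests, gene-set enrichment, and
module-overlap tests, so all p-values are numerically consistent.
BH correction runs within each family of tests; the over-targeting flag
is adj-p < 0.10.

Randomized control networks keep the miRNA set fixed and resample the
gene set uniformly without replacement from the expressed-and-targetable
universe at the observed cardinality (the randomization scheme is not
uniquely determined by the study description; gene resampling is the
default and degree-preserving edge swaps are a documented alternative,
not implemented). The default is R = 1000 replicates; summaries record R
so results against small-R regimes remain comparable. Proportions of
over-targeting miRNAs are compared with a one-sample Pearson
goodness-of-fit test against the null proportion (df = 1, no continuity
correction); this choice uniquely reproduces the published comparison of
10/41 against 49% (p ≈ 0.0016), which a two-sample test does not.

## Cross-species overlap

Overlap significance is Monte Carlo: R random draws of |A| items from the
shared universe against a fixed set B, with the add-one estimator
p = (1 + #{overlap ≥ observed})/(R + 1), so p ≥ 1/(R+1) and p = 0 is
impossible. The universe defaults to the items present on both platforms
and is user-suppliable. Direction concordance classifies each common gene
by sign agreement and reports concordant/discordant percentages.

## Signed coexpression analysis

Built from scratch on the standard signed formulation:

- similarity S_ij = (1 + cor(x_i, x_j))/2, so anti-correlation is
  dissimilarity (zero-variance genes are dropped with a warning);
- adjacency a_ij = S_ij^β with β = 12 by default; the soft threshold
  scan computes, per candidate β, the scale-free fit R² of the
  log-binned connectivity distribution (10 equal-width bins, log10
  frequency regressed on log10 mean connectivity) and picks the smallest
  β reaching the target R² (default 0.85), else the argmax;
- topological overlap TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
  with ℓ_ij = Σ_u a_iu a_uj and connectivity k excluding the diagonal;
  unsigned TOM on the signed adjacency (the TOM variant is configurable
  in principle; unsigned is the default);
- modules from average-linkage hierarchical clustering of 1 − TOM with a
  static cut at `cut_height` × the maximum merge height (default 0.99,
  interpreted as a fraction of a normalized dissimilarity scale) and a
  minimum module size (default 100). The hybrid deep-split heuristics of
  dynamic tree cutting are not reimplemented, and block-wise processing
  is unnecessary at this scale (a single block suffices);
- final assignments are refined by module membership: candidate-module
  eigengenes are computed and genes with |kME| < 0.5 return to grey.
  With few samples (here 32), chance correlations to a module profile
  (SD ≈ 1/√(n−1) ≈ 0.18) give low-connectivity satellite genes inflated
  topological overlap through the min(k) denominator, and a permissive
  static cut recruits them; the membership filter removes exactly these.
  The 0.5 threshold matches the MM > 0.5 criterion used for hub
  networks. Modules that fall below the minimum size after cleanup
  dissolve into grey;
- module labels follow the size-ordered color convention (turquoise,
  blue, brown, …; ties broken by first gene index) so outputs are
  comparable with the conventional naming;
- module eigengenes are the first right singular vector of the per-gene
  z-scored module submatrix, sign-fixed so the correlation with the
  module's mean standardized profile is non-negative (the eigengene is
  unit-norm across samples);
- gene significance GS = |cor(gene, trait)| (signed value retained
  internally and reported alongside), module membership MM = cor(gene,
  own-module eigengene); correlation p-values use the Student-t
  transform t = r√(n−2)/√(1−r²) on n − 2 degrees of freedom; the
  eigengene × miRNA correlation grid is BH-corrected as one family and
  flagged at FDR < 0.10;
- hub networks include genes with |MM| > 0.5 and GS > 0.5 (strict),
  edges weighted by adjacency, connectivity as within-subnetwork
  adjacency row sums, hub = argmax connectivity;
- two-network module correspondence cross-tabulates assignments and
  tests each cell with the shared hypergeometric kernel, BH across
  cells.

## Synthetic data generator

The generator emulates a 20-treated / 12-control study on the log2 scale:

- trait: ethanol consumption in g/kg per 3-h session; controls 0,
  treated ~ N(4.92, 0.52²) (the published cohort mean and SD);
- modules: each module has a latent profile with its stated sample
  correlation to the trait built in *exactly*; residual directions are
  chosen (Gram–Schmidt with negative inner products cancelling the
  shared trait component) so latents are mutually orthogonal whenever
  the correlation pattern allows (Σρ² ≤ 1). Module genes are
  `module_amplitude` (default 0.6 log2 units) times the latent plus
  N(0, noise_sd²) noise (default 0.2), giving within-module correlations
  ≈ 0.9; non-module genes are independent noise;
- because the consumption trait separates the groups, trait-correlated
  latents shift module genes between groups — the situation in which
  trait-correlated modules are genuinely enriched in DE genes. The
  recorded ground-truth logFC of each gene is the total expected shift
  (planted + realized latent-induced), and DE labels follow the total
  with |logFC| ≥ 0.15 as the label floor;
- planted DE: a fraction of genes (default 0.075) receives group-mean
  shifts drawn from |logFC| ∈ [0.15, 0.7] (the published effect-size
  range), upregulated with probability 0.58 (matching 413 of 709);
  planted shifts go to non-module genes first. The default fraction
  keeps the planted up/down blocks below the minimum module size — a
  block of same-direction DE genes is itself a correlated set and would
  otherwise surface as a spurious module — and yields ≈ 670 true DE
  genes, close to the published 709. miRNAs: default 300 features, 25%
  DE with up-probability 0.85 (upregulation predominant);
- interaction universe: each (miRNA, gene) pair is an edge with
  probability `baseline_edge_prob` (default 0.02), multiplied by
  `overtarget_enrichment` (default 4) for upregulated-miRNA →
  upregulated-gene pairs, capped at 1; a `validated_fraction` (default
  0.05) of edges is marked validated; predicted edges carry 4–11
  supporting tools;
- randomness: one stream per dataset, split into named substreams
  (trait, modules, expression, de_genes, edges, …) derived from
  (seed, CRC32(name)), so adding features does not shift existing draws
  and identical configs are byte-for-byte reproducible.

What the generator does **not** emulate: probe-level intensity
distributions, array batch effects, correlated measurement noise,
heavy-tailed per-gene variances, realistic miRNA family structure
(families are synthetic pairs), or biologically structured target
prediction error. Passing recovery tests therefore demonstrates the
correctness and calibration of the pipeline under its own model
assumptions, not performance on real arrays.

## Numerical choices and degenerate inputs

- Trigamma inversion by Newton iteration, 50-step cap, relative
  tolerance 1e-10; literally constant variances return a point prior at
  that value.
- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)`; k = 0
  returns exactly 1.
- TOM is symmetrized and clipped to [0, 1]; the diagonal is 1 by
  convention and excluded from connectivity sums.
- Quantile normalization uses stable argsort, making it idempotent and
  order-deterministic under ties.
- Eigengene sign for a singular module submatrix falls back to the
  single distinct profile.
- The static tree cut with `min_module_size > n` genes returns all-grey
  with a warning; an empty hub network (no gene passes the thresholds)
  returns an empty edge list with a warning rather than an error.
- Monte Carlo p-values use the add-one estimator everywhere.

## Problem sizes

Default analyses and tests run at 2000 genes × 32 samples × 300 miRNAs,
with 1000 randomized control networks and 10⁴ Monte Carlo overlap
replicates — sizes chosen so a complete run takes seconds on one core
while keeping every estimate's Monte Carlo error well below the decision
thresholds it feeds.

## Known limitations

- The static-height cut plus membership cleanup approximates, but is not
  identical to, hybrid dynamic tree cutting with deep splits; very close
  same-sign modules can merge.
- The scale-free fit uses equal-width connectivity binning; degenerate
  (all-equal) connectivity reports R² = 0 rather than failing.
- Family-name fallback matching cannot resolve genuine naming
  discrepancies between family IDs and colloquial family names; both
  routes are reported, neither asserted.
- The moderated-t assumes independent features; planted coexpression
  violates this mildly, which widens (but does not bias) the null.
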