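# mirweave

Integrative miRNA–mRNA regulatory network analysis for paired expression
studies, built around the question the alcohol-dependence literature
raised for mouse frontal cortex: when chronic binge drinking upregulates
both miRNAs and mRNAs, do the induced miRNAs preferentially target the
induced genes? `mirweave` provides the full analysis chain — moderated
differential expression, a consensus miRNA→mRNA interaction universe,
correlated bipartite targeting networks with randomized nulls and
per-miRNA "over-targeting" statistics, cross-species overlap testing, a
from-scratch signed weighted gene coexpression analysis, and
hypergeometric gene-set enrichment — plus a synthetic-data generator so
every stage is testable without any microarray download.

It is aimed at computational biologists analyzing paired
miRNA/mRNA profiles from case–control designs, and at anyone who needs a
transparent, dependency-light reimplementation of these network
statistics.

## The statistics at the core

**Moderated differential expression.** For feature *g* with pooled
two-group variance s²_g on d_g degrees of freedom, an empirical-Bayes
prior s²_g ~ s₀²·F(d_g, d₀) is fitted by trigamma moment matching; the
moderated statistic

t_g = logFC_g / (s_post,g · √(1/n₁ + 1/n₂)),  s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g)

has d₀ + d_g degrees of freedom. FDR control is Benjamini–Hochberg.

**Over-targeting.** A miRNA over-targets a DE gene set when its targets
are over-represented under hypergeometric sampling: p = P(X ≥ k) with
population N = expressed-and-targetable genes, successes n = DE genes
among them, draws K = the miRNA's expressed targets. The same kernel
drives per-mRNA over-targeting (roles swapped), gene-set enrichment, and
module-overlap tests. Network interconnectedness is the mean degree
2|E|/|V| over connected nodes, compared against gene-resampled
randomized control networks; proportions of over-targeting miRNAs are
compared by a Pearson goodness-of-fit test (df = 1).

**Signed coexpression.** S_ij = (1 + cor(x_i, x_j))/2, adjacency
a_ij = S_ij^β (β = 12), topological overlap
TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij), average-linkage
clustering of 1 − TOM with a static height cut, membership-refined
module assignment, eigengenes (first principal component per module),
module membership MM = cor(gene, eigengene), gene significance
GS = |cor(gene, trait)|, and Student-t correlation p-values.

See `docs/methods.md` for assumptions, defaults, and design choices.

## Worked example

Run the full pipeline on the default synthetic study (20 treated vs 12
control samples, 2000 genes, 300 miRNAs, four planted trait-correlated
modules, 4× up–up targeting enrichment):

```sh
mirweave run --seed 1 --out results/
mirweave report --report results/report.json
```

which prints:

```
Differential expression: 223 genes up, 177 down (FDR < 0.01); 60 miRNAs up, 30 down (FDR < 0.1)
Interaction universe: 13340 edges, 300 miRNAs, 1997 genes
Positive network: mean degree 7.41637 vs null 3.551418 (SD 0.196117); over-targeting 60/60 miRNAs
Negative network: mean degree 2.244681 vs null 3.315731 (SD 0.209134); over-targeting 0/60 miRNAs
Positive vs null proportion 0.001: chi2 p = 0 (enriched)
Negative vs null proportion 0.001: chi2 p = 0.784 (depleted)
Cross-set family overlap: 55 of 55 detected vs 59 reference families (Monte Carlo p = 0.0001, R = 10000)
Coexpression: 4 modules (grey: 1453 genes) at beta = 12.0
  module turquoise: trait r = +0.653 (p = 5.17e-05), DE genes 170/173 (enrichment p = 5.1e-129)
  module blue: trait r = -0.586 (p = 0.00042), DE genes 132/152 (enrichment p = 2.34e-78)
  module brown: trait r = +0.459 (p = 0.0083), DE genes 14/122 (enrichment p = 0.996)
  module yellow: trait r = -0.445 (p = 0.0107), DE genes 0/100 (enrichment p = 1)
  hub of turquoise: Gene0089 (164 genes pass MM/GS thresholds)
```

Reading this: the *positive* network (upregulated miRNAs × upregulated
genes) is roughly twice as interconnected as its randomized control
(7.42 vs 3.55, far beyond 3 null SD) and every tested miRNA
over-targets the upregulated set, while the *negative* network is
indistinguishable from — here slightly below — chance, exactly the
asymmetry the generator plants. The four planted modules are recovered
with their trait correlations (±0.45–0.65), the two strongest are
almost entirely composed of differentially expressed genes, and the
remaining noise genes fall into grey. Reports are byte-identical across
reruns with the same seed.

Every stage is also available separately (`simulate`, `de`, `universe`,
`overtarget`, `crossspecies`, `coexpress`, `enrich`), reading and
writing plain TSV/GMT files, and as library functions
(`mirweave.fit_moderated_t`, `mirweave.mirna_overtargeting`,
`mirweave.topological_overlap`, …).

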