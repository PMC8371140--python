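# organoidbench

How much of the in-vivo intestinal transcriptome survives organoid culture?

Intestinal organoids grown from isolated crypts are a workhorse in-vitro
model, but it is rarely quantified *which* biological features of the source
tissue they retain: regional identity along the gut (oral/duodenum,
intermediate/jejunum, aboral/ileum), sex differences, and aging signatures.
`organoidbench` implements, as a tested and fully reproducible pipeline, the
statistical machinery needed to answer that question from bulk and
single-cell RNA-seq of a crypt-vs-organoid factorial study — together with a
synthetic data generator that plants known effects so every stage can be
scored against ground truth without any external download.

It is aimed at computational biologists who run or evaluate organoid
RNA-seq studies, and at methodologists who want a ground-truthed sandbox for
variance partitioning, deconvolution and effect-size analyses.

## What it computes

Given a genes × samples count matrix with a factorial sample sheet
(sample_type × compartment × gender × age × replicate) and labelled
single-cell counts:

1. **Normalization and differential expression.** Median-of-ratios size
   factors, *s_j* = median_g ( *c_gj* / geomean_g ), and a per-gene
   negative-binomial Wald test on the log ratio of normalized group means.
   The NB is parameterized as Var = μ + αμ²; per-gene α is estimated by
   method of moments and shrunk 50% toward an *a₀ + a₁/μ* mean–dispersion
   trend. BH step-up controls the FDR within each contrast.
2. **Variance partitioning.** Genes are kept when the IQR of
   log2(normalized + 1) exceeds 1.5 and the mean normalized count exceeds 10
   in more than 3 of the 24 condition groups; PCA on centered, unit-scaled
   genes (the `prcomp(scale.=TRUE)` convention); per-gene contribution to a
   component is 100·loading²; highly-contributing genes pass
   log2(contribution) ≥ −3.32; PC–factor association by Welch's *t* (two
   levels) or one-way ANOVA (three or more).
3. **Cell-type reference.** Single cells are depth-normalized to the median
   total and log10-transformed, clustered by best-of-10 k-means on the top
   20 PCs, typed by marker-set z-scores, and per-cluster markers are genes
   with log2FC ≥ 2 and BH-adjusted p < 0.05 vs all other cells. The
   signature matrix holds mean linear-scale marker expression per type.
4. **Deconvolution.** Each bulk sample, restricted to signature genes, is
   decomposed by non-negative least squares into cell-type proportions
   (renormalized to sum to 1). A simulated-mixture validation draws known
   Dirichlet compositions, adds multiplicative log-normal noise, and reports
   the pooled squared Pearson correlation between estimated and true
   proportions. Group shifts are tested by Welch's *t* and one-way ANOVA.
5. **Enrichment.** Weighted running-sum enrichment score (the
   Kolmogorov–Smirnov-like walk: hits add |r|^w normalized over hit weights,
   misses subtract 1/(misses)), permutation p-values with plus-one
   correction, BH across sets; plus directional per-group mean z-scores for
   up/down-signed gene sets.
6. **Effect sizes.** DEG matrices (log2FC where significant, exactly 0
   elsewhere) feed OLS models whose adjusted R² —
   1 − (1 − R²)(n − 1)/(n − k − 1) — measures how much of an in-vivo
   feature's DEG vector is explained by its in-vitro counterpart
   ("retention"), and how much compartment/gender explain aging log2FCs
   across strata. Model quality is assessed by the F-test.

The synthetic generator (`organoidbench.simulate`) produces the whole study:
a 2×3×2×2 factorial with 4 replicates (96 bulk samples), per-factor planted
log2 fold-changes on disjoint gene sets with controllable variance shares
and in-vitro sharing, bulk samples mixed from eight intestinal epithelial
cell-type profiles (Stem, TA, late enterocyte progenitor, enterocyte,
enteroendocrine, goblet, Paneth, tuft) with condition-dependent Dirichlet
compositions, and NB counts with per-gene dispersion and per-sample library
size — plus the full ground truth for scoring.

## Worked example

```python
from organoidbench import SimulationConfig, run_all, report_summary

run_all(SimulationConfig(seed=5), "run")
print(report_summary("run"))
```

prints (abbreviated):

```
== Design ==
samples: 96  cells: 480

== Variance decomposition ==
PC1: 62.2% of variance, 191 contributing genes
PC2: 15.8% of variance, 50 contributing genes
PC3: 4.4% of variance, 15 contributing genes
...

== Cell-type composition ==
crypt: Enterocyte 0.28, TA 0.16, Goblet 0.15
organoid: TA 0.31, Stem 0.30, Enterocyte 0.11
simulated-mixture R^2 = 0.998; bulk-recovery R^2 = 0.950

== Cell-type enrichment (GSEA) ==
Enterocyte: ES -0.93, adj p 0.00133
Stem: ES +0.94, adj p 0.00133
...

== Effect sizes (feature retention in vitro) ==
age: adjusted R^2 = 0.515 (n = 30, F p = 4.89e-06)
compartment: adjusted R^2 = 0.746 (n = 85, F p = 1.13e-26)
gender: adjusted R^2 = 0.275 (n = 53, F p = 3.29e-05)
```

Read: PC1 (culture vs tissue) dominates the transcriptome; the
undifferentiated stem/TA compartment expands in organoids at the expense of
differentiated lineages (positive stem ES, negative enterocyte ES, large
composition shift); and of the three biological features, regional
(compartment) identity is retained best in vitro, sex differences worst —
exactly the planted structure of the generator's defaults.

The same stages are available as CLI verbs
(`organoidbench simulate|de|varpart|signature|deconv|gsea|all|report`,
common flags `--config config.yaml --seed N --out DIR`).

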