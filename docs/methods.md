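# Methods

This note documents the models behind `organoidbench`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical conventions a user should know before trusting or extending the
results.

## The synthetic study

The generator emulates a crypt/organoid comparison with a full factorial
design: sample_type {crypt, organoid} × compartment {oral, intermediate,
aboral} × gender {male, female} × age {young, old} × 4 replicates = 96 bulk
samples, plus labelled single-cell data (60 cells for each of eight
intestinal epithelial cell types by default).

**Expression model.** Each gene carries a baseline relative abundance drawn
once from log-normal(0, 1). Every cell type owns a disjoint block of 25
marker genes on which its profile is lifted by 2⁴ (any value ≥ 2³ preserves
the planted marker separation the reference-building stage is scored
against). A bulk sample's expected expression is

μ_gj = [ Σ_k p_jk · profile_gk ] · 2^(Σ_f β_gf · w_f(level_j)) · L_j / Z_j

where p_j ~ Dirichlet(condition concentration), β_gf is the planted log2
fold-change of gene g for factor f, w_f places the factor's levels on a
linear 0→1 gradient (so a three-level factor interpolates oral →
intermediate → aboral), L_j ~ Uniform(3·10⁵, 6·10⁵) is the library size and
Z_j normalizes the expected total. Counts are NB(μ, α) with
Var = μ + αμ²; per-gene α ~ log-normal(log 0.05, 0.5), floored at 10⁻⁴
(α < 10⁻¹⁰ falls back to Poisson sampling). This mean–dispersion scale is
typical of bulk RNA-seq with good replicates.

**Planted effects.** Per factor, a fraction of genes (defaults: sample_type
12%, compartment 4%, gender 2.6%, age 1.4% of 2000 genes) receives
|log2FC| ~ N(2, 0.5) (clipped at 0.25) with random sign; affected sets are
disjoint across factors and exclude marker genes, so expression effects and
composition effects remain separable when scoring. `variance_targets`
(default 60/20/13/7% for sample_type/compartment/gender/age) rescales each
factor's magnitudes exactly so the realized shares of planted log2-variance
match; the affected-gene *counts* are allocated roughly proportionally as
well, because PCA standardizes genes and therefore sees shares through gene
counts × per-gene signal purity rather than raw magnitudes. With both knobs
set from the targets, PC1's variance fraction tracks the sample_type share
to within a few points.

**In-vitro sharing.** Each affected gene's effect is also active in
organoid samples with probability `shared_in_vitro` (defaults: compartment
0.8, gender 0.3, age 0.5; the sample_type axis itself is always active).
These defaults encode the qualitative hierarchy reported for cultured
crypts — regional identity is retained best, sex differences worst, aging
in between — and give the retention stage a non-trivial planted answer. The
retention adjusted R² approximately recovers the shared fraction.

**Compositions.** Dirichlet concentrations are proportions × 200 (small
sampling noise). Crypt-like samples are enterocyte-dominated (Stem 0.10,
TA 0.15); organoid-like samples are stem/TA-expanded (0.30/0.30), emulating
the expansion of undifferentiated cells in culture. A composition-neutral
mode (`SimulationConfig.null()`, or any shared `composition_spec`) separates
expression effects from composition effects.

**Randomness.** All stages draw from named substreams
(`profiles`, `effects`, `dispersion`, `bulk`, `sc`) derived from one root
seed via a BLAKE2 digest of the stage name, so any stage is reproducible in
isolation and identical configs give byte-identical outputs.

**What the generator does not emulate:** gene length/GC biases, UMI and
droplet artifacts (doublets, ambient RNA), batch effects beyond the declared
factors, correlated gene modules beyond the planted blocks, and
interactions between factors (aging effects are the same in every
compartment/gender stratum). Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under a realistic NB
factorial world — not that any particular biological conclusion transfers
to real tissue.

## Differential expression

The test is deliberately minimal: per gene, the Wald statistic is the log
ratio of size-factor-normalized group means over its delta-method standard
error, with the NB variance function Var(c/s) = q/s + αq². Dispersion is
method-of-moments on within-group residuals, solved from
E[S²] ≈ q·mean(1/s) + αq², floored at 10⁻⁸ and shrunk 50% toward a fitted
a₀ + a₁/q trend (a₀, a₁ ≥ 0). A pseudocount of 0.5 on the normalized group
means keeps the log ratio finite; at base means ≥ 100 its bias is
negligible. All-zero genes are flagged untested rather than dropped.
p-values are two-sided normal; with ≥ 4 samples per group the null
type-I error at α = 0.05 sits inside [0.035, 0.065] on 2000-gene null
simulations, and the p-distribution passes a KS check against U(0, 1).
There is no outlier replacement, no independent filtering and no fold-change
shrinkage: downstream stages consume only (log2FC, p, adjusted p), and the
stated calibration is the contract.

Contrast conventions: compartment is tested aboral vs oral (oral the
reference); the intermediate level enters only composition and ANOVA
analyses. Stratified contrasts (e.g., old vs young within
organoid/oral/male) are separate two-group fits, not one interaction model.

## Variance partitioning

The gene filter computes the IQR on log2(normalized + 1) — a raw-count IQR
would be dominated by expression level — and reads "more than 3 conditions"
as strictly greater than 3 of the 24 factor combinations (both thresholds
configurable). PCA centers and unit-scales genes (ddof = 1) and decomposes
the samples × genes matrix by SVD; variance fractions are eigenvalues over
the number of retained genes, so they sum to 1 across all computable
components; contributions are squared loadings in percent and sum to 100
per component. Sign convention: the gene with the largest |loading| in each
component is made positive, which fixes the otherwise arbitrary SVD signs.
The contributing-gene cutoff log2(contribution) ≥ −3.32 (≈ 0.1%) is the
default; a density-based alternative (knee of the sorted log2-contribution
curve, maximum distance to the chord) is available as `mode="knee"`.
Whether to log-transform before PCA is a flag, defaulting to log.

## Cell reference and deconvolution

Cells are scaled to the median per-cell total (so the median cell is
unchanged) and log10(x + 1)-transformed. k-means (best inertia of 10 starts,
seeded) runs on the top 20 PCs of the log matrix; a targeted re-clustering
helper splits one cluster with k = 2 for types that co-cluster. Cluster
typing takes the marker set with the highest mean z-scored expression and
reports the runner-up margin; ties within 10⁻⁹ are flagged ambiguous rather
than broken silently. Marker definition uses Welch's t on log-normalized
values with the selection rule log2FC ≥ 2 AND BH-adjusted p < 0.05; the
fold change is computed on linear means with a 0.1 pseudocount. The
signature stores mean *linear*-scale normalized expression because bulk
mixtures combine linearly; deconvolution is non-negative least squares with
renormalization to the simplex, which is scale-invariant in the bulk vector
and equivariant under signature column permutations. A support-vector
formulation could be swapped in behind the same interface; NNLS was chosen
as the reproducible core. The mixture-validation noise model is
multiplicative log-normal with mean 1 and a configurable coefficient of
variation — a declared choice, since no canonical noise model exists for
such validations; the pooled R² over all (mixture, type) pairs is the
headline number, with per-type R² reported alongside.

## Enrichment

The running-sum statistic increments on set hits by |r|^w normalized over
hit weights (w = 1 by default; w = 0 reduces exactly to the classic
two-sample KS statistic, which the tests exploit as an oracle) and
decrements on misses by 1/(list − set size). The ES is the signed maximum
absolute deviation; permutation nulls redraw |S| random genes per round and
the p-value is plus-one corrected, (1 + #{|ES₀| ≥ |ES|})/(n + 1), so it is
never zero. Gene-label permutation (rather than phenotype permutation) is
the default null, matching common pre-ranked practice; ranking defaults to
the Wald statistic with lexicographic tie-breaking for determinism.
Normalized enrichment scores with set-size renormalization are out of
scope.

## Effect sizes

DEG matrices zero-fill non-significant entries and drop genes significant
nowhere before model fitting — all-zero rows carry no information and only
deflate R² (keeping the full union is a flag). Two significance rules are
first-class: adjusted p < 0.05 (retention models) and raw p < 0.05 (the
aging-modifier models, which otherwise run out of DEGs in sparse strata);
the rule used is recorded on the matrix. Retention fits in-vivo log2FC on
in-vitro log2FC per feature (simple) and on all three features (combined);
aging-modifier models stack the per-stratum aging matrix to long form and
regress on compartment/gender indicator dummies. Raw log2FCs are used
without rescaling — adjusted R² is scale-invariant for a single predictor.
Collinear predictor pairs and constant outcomes are rejected with named
errors rather than silently producing degenerate fits.

## Problem sizes and tolerances

The default study — 2000 genes × 96 samples, 480 cells — was chosen so the
whole pipeline, including 1000-permutation GSEA, completes in a few seconds
while keeping ≥ 20 affected genes per factor for stable recovery
statistics. Calibration windows (type-I error in [0.035, 0.065], GSEA null
fraction in [0.02, 0.08] over 200 sets) are three-or-more-sigma binomial
bands around the nominal 5% at these sizes. Composition rows are validated
to sum to 1 within 10⁻¹²; PCA variance fractions to 1 within 10⁻⁹;
contributions to 100 within 10⁻⁶. Size factors (and hence normalized
counts) are defined up to one global scalar — only factor ratios are
identifiable — and all tests and downstream statistics respect that.

## Known limitations

The DE engine is not a DESeq2 reimplementation and will disagree with it
gene-by-gene, particularly at low counts; only (log2FC, p, padj) behaviour
is contracted. The deconvolution solver is NNLS, not the support-vector
regression of CIBERSORTx-style tools. Aging interactions are not planted,
so aging-modifier effect sizes on default synthetic data are near zero by
construction. Real-data idiosyncrasies (outlier samples, hidden batches,
compositional biases of sequencing) are outside the generator's world and
must be assessed on real inputs.
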