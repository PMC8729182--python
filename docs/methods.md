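# Methods

## Model

For one pathway, let p₁,…,p_G be p-values from G independent single-omics
pathway analyses. The order-r MiniMax statistic is the r-th order
statistic p₍ᵣ₎, equivalently the minimum over all r-subsets of the subset
maximum. If the per-omics p-values are independent Uniform(0,1) under the
joint null ("the pathway is null in every omics type"), p₍ᵣ₎ ~
Beta(r, G − r + 1), so the statistic's p-value is the regularized
incomplete beta function at the observed value. For the default r = 2,
G = 3 this is Beta(2,2) with CDF 3x² − 2x³. Rejection therefore requires
at least r platforms to show signal, which is what distinguishes the
statistic from Fisher/Stouffer-style combiners that a single extreme
platform can dominate.

Assumptions worth stating: (i) the per-omics pathway tests are valid
(uniform under their own nulls) — the integrator inherits any
miscalibration of its inputs; (ii) independence across omics for the
theoretical null. Assumption (ii) is relaxed by the empirical mode below.

### Missing p-values

A pathway absent from some omics analyses is integrated over its
non-missing entries with a per-pathway effective count g_eff, using
Beta(r, g_eff − r + 1). This preserves per-pathway null uniformity at the
cost of comparing pathways calibrated against slightly different nulls;
g_eff is reported in the output so such rows are visible. Pathways with
fewer than r non-missing values are skipped and logged, never silently
dropped. Contributing omics (the r smallest p-values) break ties by input
column order, making output deterministic.

### Empirical null

When raw data are available, phenotype labels are permuted and per-omics
pathway p-values recomputed; the collected null MiniMax statistics are
pooled globally (across pathways and permutations) and a Beta distribution
fitted by maximum likelihood (method-of-moments start, L-BFGS-B, both
shapes bounded to [0.01, 100], values clamped to (1e−12, 1−1e−12)).
Positive cross-omics correlation pushes both fitted shapes below their
theoretical values (α̂ < r, β̂ < G − r + 1); in the perfectly correlated
limit the order statistic is uniform, Beta(1,1).

Permutations shuffle labels independently per omics dataset by default,
mirroring the unmatched-samples design. That choice also *removes*
cross-omics p-value correlation from the null, so for matched designs a
`share_labels` option applies one permutation to all layers and preserves
the correlation the empirical null exists to capture — this is the mode
the correlated-omics tests use. The fitted null applies to complete rows
(g_eff = G); rows with missing entries fall back to their theoretical
Beta, which the provider makes explicit.

## Single-omics pathway scoring

The built-in test standardizes each gene (mean 0, SD 1, ddof = 1,
zero-variance genes dropped with a log entry), extracts the first plain
principal component of the samples over the pathway's genes (sign fixed so
the largest-magnitude loading is positive), and tests the score against
the phenotype: logistic likelihood-ratio test (binary; LRT rather than
Wald for small-sample behaviour, p floored at 1e−300 on perfect
separation), linear-regression slope t-test (continuous), or a
proportional-hazards score test with Breslow tie handling (survival; for a
binary covariate it reduces to the log-rank test, which is how it is
cross-checked). A plain PC1 is used deliberately in place of sparse or
adaptive PCA variants: the integrator only requires valid per-omics
pathway p-values, and users with platform-specific tools should prefer
them and feed p-values directly.

## Simulation benchmark

The generator emulates a multi-omics cancer-subtype benchmark at desk
scale. Defaults, chosen once as realistic study conditions: 3 omics layers
measuring the same 300 genes on 150/100/80 unmatched samples; genes are
grouped into latent blocks (~6 genes) whose members load on a shared
per-subject factor with weight √ρ, ρ = 0.3, giving within-block
correlation ρ; matched subjects (controlled by an `overlap` fraction)
reuse factors across layers, carrying cross-omics correlation. Synthetic
pathways are then re-derived from the data itself: each layer is
standardized, layers are stacked by columns, and genes are partitioned
into 50 clusters by Ward hierarchical clustering using the Lance–Williams
"ward.D" update on unsquared Euclidean distances — implemented by running
the ward linkage on the square roots of the distances, which reproduces
ward.D merge order exactly because ward linkage squares its input (this is
verified against R's `hclust(method="ward.D")` in the test suite; it is
*not* the ward.D2 variant). Five clusters are declared true positives.

Each of the (default 100) replicates draws fresh Bernoulli(½) group
labels per subject and adds the effect μ to round(prop × size) genes
(round half away from zero; gene subset seeded per replicate, identical
across layers) of each true pathway for group-A samples only. Replicate
seeds derive from the scenario seed alone — not from μ or prop — so
scenarios differing only in effect size share base data and labels
(common random numbers), which is what the power-monotonicity test leans
on. Scoring and integration then run exactly as in a real analysis.
Metrics: type-I error = fraction of null-pathway MiniMax p-values < 0.05;
AUC = Mann–Whitney concordance of ranking true vs null pathways by
p-value (ties count half), averaged over replicates. The grid μ ∈
{0,…,0.5} × prop ∈ {0.2,…,0.8} mirrors the standard design; the null run
uses 100 replicates × 50 pathways = 5,000 draws.

What the generator does not emulate: heavy-tailed and discrete omics
distributions, gene-level measurement platforms with unequal feature
density, batch structure, and realistic pathway overlap (synthetic
pathways partition the genes). Passing benchmarks therefore demonstrate
calibration and ranking behaviour of the statistic under controlled
correlation, not performance on any particular real dataset.

## Gene-size bias correction

Feature-level statistics (SNPs/CpGs) are assigned to every gene whose
span ± a 5 kb window (inclusive bounds; gene start/end stand in for first
/last exon when exon annotation is absent) contains their position;
multi-assignment is allowed. Each gene is summarised by its smallest
feature p-value and feature count n_links, with score y = −log10(min p)
(p = 1 clamped to 1 − 1e−16). Since the minimum of n uniforms has mean
1/(n + 1), y grows with n_links under the null; the correction fits a
gamma-family GLM (log link — y is chi-square-like under the null) with a
cubic B-spline smooth of n_links (df = 4, configurable) and keeps
residuals as size-adjusted scores. Residual type defaults to "response"
(y − fitted mean); "deviance" is available. When genes have too few
distinct n_links values for the spline, the fit degenerates gracefully to
an intercept-only gamma GLM (centered scores).

## Numerical choices and edge cases

- Statistics are used as-is for ranking; only Beta CDF evaluation clamps
  to [1e−300, 1 − 1e−16]. CDF endpoints return exactly 0 and 1.
- Output ordering is fixed (ascending p-value, ties by pathway ID) and
  the result TSV carries both full-precision and 3-significant-figure
  scientific display columns, so reruns are byte-identical.
- BH-FDR (Benjamini–Hochberg step-up, via statsmodels) is applied once
  across all integrated pathways of a run.
- Default pathway-size filter at scoring: 3–200 genes.
- Every stochastic routine takes an explicit seed; benchmark sub-seeds
  are spawned from a SeedSequence.

## Known limitations

- The theoretical null assumes independent platforms; with substantially
  correlated layers it is anti-conservative and the empirical mode should
  be used (which requires raw data).
- The global empirical Beta fit assumes exchangeable pathways; very
  heterogeneous pathway sizes could argue for stratified fits, which are
  not implemented.
- The statistic discards effect directionality and magnitude; a pathway
  up-regulated in one layer and down in another integrates identically.
- Gene-span feature assignment is windowed and LD-agnostic.
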