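# Methods

This note documents the models, conventions and design decisions behind
`glycoindex`, in the order the pipeline runs them.

## GSEA (module `gsea`)

**Ranking.** Genes are ranked case-vs-control by signal-to-noise,
(μ_case − μ_ctrl)/(σ_case + σ_ctrl), with each group's standard deviation
floored at max(0.2·|μ|, 0.2) — the classic GSEA variance floor, which keeps
near-constant genes from dominating the ranking. A moderated-t metric
(delegating to the differential-expression module) is available for very
small groups. Published applications of GSEA rarely state the metric; the
signal-to-noise default is a documented assumption, as are the defaults
below. Ties break by gene symbol ascending so rankings are identical across
platforms.

**Running score.** The weighted Kolmogorov–Smirnov form: at position i,
P_hit accumulates |r|^p over set members (normalized by the set total) and
P_miss accumulates 1/(N − N_hit) over non-members; the ES is the signed
largest absolute deviation of P_hit − P_miss, earliest position on ties.
Weight p = 1 by default. If every set member has |r|^p = 0 the statistic
degenerates, and the implementation falls back to weight 0 for that set
with a warning. The curve ends at exactly 0 (both ECDFs reach 1), which the
tests assert.

**Leading edge.** For ES > 0, set members at or before the peak; for
ES < 0, at or after the trough (the extremum position is included on both
sides — the standard convention); an ES of exactly 0 has an empty leading
edge.

**Significance.** The default null permutes set membership over the ranked
universe ("gene" scheme, matching the fast preranked backends of the common
GSEA wrappers); a phenotype-permutation scheme (permute group labels,
re-rank) is available. NES = ES / mean(|null ES| of matching sign);
p = (1 + #{same-sign nulls with |null| ≥ |ES|}) / (1 + #same-sign nulls).
When no null shares the observed sign, p = 1 and the NES is flagged
degenerate. Identical seeds give identical null ensembles per set, so
duplicate sets yield byte-identical results. FDR is Benjamini–Hochberg
across the collection.

## Core set and glycolysis index (module `index`)

A gene is "leading in dataset d" if it appears in the leading edge of at
least one gene set in d that passes the direction filter (default: ES < 0,
i.e. downregulated — the regime the index targets) and the FDR filter
(default ≤ 0.05; nullable, since published pipelines do not always state
whether significance was required before harvesting leading edges). Genes
leading in ≥ min_datasets datasets (default 2, "at least half" of a
four-dataset design) form the core set. Pooling is monotone: lowering
min_datasets never removes a gene.

The index is the Barbie-style *integrated* ssGSEA enrichment score of the
core set — the sum over all positions of the weighted in-set rank ECDF
minus the uniform out-of-set ECDF, with α = 0.25 (the default of the
common ssGSEA implementations) — not the running-sum extremum. Within-sample
ties break by (value descending, symbol ascending), a deterministic stable
sort rather than average ranks, keeping the weighted sum well defined.
Samples are scored independently; the raw ES is the default index
(range normalization across samples, dividing by max − min, is available
but off by default since it makes scores depend on the cohort). The
median split assigns each sample low/high relative to its *region's*
median, ties to low; a single-sample region is labeled low with a warning.

## Differential expression (module `diffexpr`)

Implemented natively rather than wrapping the reference R implementation:
per-gene ordinary least squares against a shared design — intercept,
contrast indicator (case or high-index = 1), region dummies (reference =
first region alphabetically), sex (M = 1), and a natural cubic spline of
age with one degree of freedom (boundary knots at the observed min/max;
with no interior knots the natural constraints make the basis exactly
linear) — followed by empirical-Bayes moderation: the scaled
inverse-chi-square prior (d0, s0²) is estimated by method of moments on
log s_g² using digamma/trigamma identities, with the trigamma equation
inverted by Newton iteration (tolerance 1e-8) and d0 capped at 1e6
(effectively infinite pooling when the observed spread of log-variances is
at or below its sampling expectation). Moderated t = log2FC /
(s̃_g √v_contrast) with d0 + d_g degrees of freedom. The test suite
cross-checks coefficients, moderated t, p-values and (d0, s0²) against
Bioconductor limma to ~1e-9 on a random dataset. Trend and robust variants
are not implemented.

DEG filters are strict inequalities (FDR < 0.05 AND |log2FC| > 0.5), and
the two contrasts' DEG lists are intersected. The high-vs-low contrast is
fit on case samples only, re-splitting their indices at the per-region
median.

One caveat found during development: BH step-up adjusted p-values are *not*
an idempotent transform (p = [1.0, 0.25] adjusts to [1.0, 0.5], which
re-adjusts to [1.0, 1.0]); only all-tied vectors are fixed points. The
tests therefore assert exactness against the step-up formula and order
invariance, not idempotence.

## Over-representation analysis (module `ora`)

One-sided hypergeometric enrichment, p = P(X ≥ k) with
X ~ Hypergeometric(N, K, n), restricted to a caller-supplied background
(the pipeline uses the genes measured in every dataset). Annotation
databases are user-supplied GMT files — nothing is bundled, so term counts
never depend on a packaged database version. Gene identifiers are symbols
throughout; no ID conversion is performed.

## Microenvironment (module `microenv`)

Two abundance estimates with different assumptions:

* **Marker ssGSEA** — the enrichment score of a cell type's marker genes,
  a rank-based *relative* proxy robust to scale but not a proportion.
* **NNLS deconvolution** — non-negative least squares of de-logged
  expression (2^x − 1, matching the log2(x+1) convention of the mixture
  generator) on a linear-scale signature matrix. This is a transparent
  reference method, not a reimplementation of the heavier ν-SVR/ensemble
  deconvolution suites; `absolute` mode returns raw coefficients,
  `relative` rescales each sample to sum to 1 (an all-zero solution becomes
  uniform with a warning).

Group comparisons use two-sided Wilcoxon rank-sum tests — exact when the
combined n ≤ 20 and tie-free, normal approximation with tie correction
otherwise (documented because p-values near a threshold can depend on the
switch) — reported as directed log p = sign(median_case − median_ctrl) ·
(−log10 p). Correlations with the index use Spearman's rho with the
two-sided t approximation. Covariate-adjusted associations fit
y ~ x + covariates by least squares or logistic regression (via
statsmodels; iteration cap 50, tolerance 1e-8) and report the Wald
statistic for x; perfect separation is returned as a failed result with a
NaN p-value rather than raised.

## Consensus network (module `network`)

Spearman rho for every (glycolysis gene, marker gene) cross pair per
dataset, BH-corrected *within* each dataset (each dataset is its own test
family, matching the per-dataset analysis; pooling families across datasets
would change the thresholds and is deliberately not done). Constant genes
make their pairs untestable: excluded from the BH denominator, never
significant. Evidence per pair = the four per-dataset significance flags
(FDR < 0.05, strict) plus PPI membership (score strictly > 0.7; STRING-style
0–999 scores must be rescaled, 700 ↔ 0.7). A pair is retained at
support ≥ 4 of 5 with sign agreement evaluated over the *significant*
datasets only (the literal reading of "identical directions in all datasets
with significant results" — non-significant datasets carry no direction).
A pair missing from a dataset gets a false flag, keeping the five-channel
arithmetic intact; a PPI-only pair has no sign and is dropped. The result
is invariant to dataset and pair ordering.

## Synthetic data (module `simulate`)

The generator emulates the pipeline's target study design: four
region-stratified case/control cohorts on one gene universe, Gaussian on
the log2 scale (normalized microarray intensities are approximately
Gaussian in log space; no count model). Defaults define the study
conditions used by the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | universe size (50-gene glycolysis block + 48 markers + filler) |
| n_per_group | 30 | cases and controls per region (n = 60/dataset) |
| planted_set | 30 genes | shifted by `effect_size` in cases |
| effect_size | −0.8 log2 | planted downregulation |
| noise_sd | 0.5 log2 | i.i.d. residual noise |
| pathway_factor_sd | 0.5 log2 | per-sample latent activity shared by planted genes |
| age_effect | 0.01 /yr | slope on a random 10% of genes; ages ~ U(60, 95) |
| sex_effect | 0.2 log2 | shift on a random 5% of genes; sexes balanced |
| coexpr_pairs | 10 pairs at ρ=0.7 | planted glycolysis–marker correlations |

The latent pathway factor models co-regulation of pathway genes, without
which a median split on the index would select only on independent noise
and the high-vs-low contrast could never produce |log2FC| > 0.5 genes; its
magnitude is set comparable to the residual noise. The planted
co-expression pairs source from glycolysis-universe genes *outside* the
planted set — coupling a marker to a factor-sharing planted gene would
correlate it with the entire planted block and the pairwise ground truth
would no longer describe the data. Mixture samples are linear combinations
of a signature matrix with multiplicative log-normal noise, then
log2(x+1), with ground-truth proportions recorded.

What the generator does **not** emulate: empirical mean–variance profiles
of real microarrays, batch effects, probe-level artifacts, correlated
marker co-expression beyond the planted pairs, or single-cell data. Passing
tests therefore demonstrate correctness and calibration of the machinery
under a controlled generative model, not performance on real cohorts.

All outputs are pure functions of (config, seed); fixture bundles are
byte-identical across runs.

## Pipeline determinism and problem sizes

The pipeline writes only deterministic artifacts (TSV/GMT/SIF/JSON, with a
config-hash manifest); the run log is the single exception (wall times).
Identical config + seed therefore give byte-identical outputs, asserted by
SHA-256 in the tests.

Problem sizes in the validation suite — 2000-gene universes, 30–40 samples
per group, 500 permutations, 200 null gene sets, 1000 random BH vectors,
every hypergeometric instance with N ≤ 30 — were chosen as the smallest
scales at which the distributional claims (KS uniformity, binomial error
bands) have meaningful power; all are set in the test/acceptance code, not
tuned to outcomes.
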