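# Methods

This note documents the models and procedures implemented in `mircluster`,
the parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken where the
underlying description left the design open.

## Genomic cluster detection

**Definition.** A miRNA cluster is a group of at least `min_cluster_size`
(default 4) annotated mature miRNAs whose total genomic span (max end − min
start) is at most `window_bp` (default 1,000,000 bp) on one chromosome. The
−5p and −3p arms of a hairpin are separate members. Coordinates are 1-based
inclusive throughout (GFF3 convention); BED inputs are shifted at the
boundary.

**Algorithm.** Per chromosome, records sorted by (start, end, name) are
chained greedily left to right: a record joins the open chain iff adding it
keeps the chain's span within the window; otherwise the chain closes and a
new one opens. This is equivalent to repeatedly taking the maximal
window-fitting run that starts at the leftmost unassigned record, which is
exactly what the brute-force oracle in the test suite computes. Consequences:
each miRNA belongs to at most one cluster, the clustered + unclustered names
partition the input, and the output is translation-invariant and
deterministic (ties broken by end then name). Clusters are numbered by
(chromosome order, span start), with natural chromosome ordering (numeric,
then X/Y).

*Window semantics.* "Within a 1 Mb window" admits several readings (sliding
window, max gap, total span). Total span via greedy chaining was chosen: the
13 published clusters all span under 60 kb, so every reasonable reading
reproduces them, and span-chaining is the simplest semantics with a clean
partition property. Both the window and the minimum size are configurable.

**Host relation.** Clustering ignores strand; a cluster's dominant strand is
the majority strand of its members. A cluster is *sense-intronic* if a gene
on the dominant strand fully contains its span (smallest such gene wins),
*antisense* if the only overlapping genes are on the opposite strand
(largest overlap wins), *intergenic* if no gene overlaps, and *unknown* when
gene annotation is absent or only a partial same-strand overlap exists (the
one configuration with no clean biological reading).

## Expression matrices

* **Expression filter:** keep miRNAs with > 0 reads in at least
  `ceil(min_fraction × n_samples)` samples (default 1/4 — with 12 samples the
  threshold is 3 either way; ceiling implements "at least" conservatively).
* **Correlation filter:** restrict to baseline (untreated) samples and keep
  miRNAs with > 0 reads in at least `min_present` of them (default 5, for 6
  baseline samples). "Some expression" is read as count > 0, the same
  operator as the DE filter. Both filters are idempotent.
* **TPM:** `rate = count / length`, scaled so each sample sums to 10^6.
  All-zero samples are left at zero with a warning.
* **PCA:** rows (miRNAs) are mean-centered and the matrix decomposed by SVD
  across samples, matching the use of PCA to separate samples; variance
  fractions are `s_i² / Σ s²`. Sign convention: the largest-magnitude miRNA
  loading of each component is made positive, so output is deterministic.

Read counting assigns each alignment to the miRNA it overlaps by at least
`min_overlap_frac` (default 0.5) of the read length; ties go to the larger
overlap, then the leftmost miRNA.

## Differential expression

The DE stage is a common-dispersion negative-binomial GLM analysis, the
classic count-model recipe:

1. **TMM normalization.** Reference sample = column whose 75th-percentile
   count fraction is closest to the mean. Per sample, gene-wise
   M = log2 ratio and A = mean log2 abundance versus the reference over
   genes positive in both; trim 30% of M per tail and 5% of A per tail
   (`trim_m`, `trim_a`); average the surviving M with inverse
   delta-method-variance weights; rescale factors to geometric mean 1.
   A test cross-checks the implementation against edgeR's
   `calcNormFactors` via Rscript (agreement ~1e-8 on fixtures).
2. **Common dispersion.** One dispersion φ shared by all genes, maximizing
   the Cox–Reid adjusted profile log-likelihood
   `Σ_g [ ℓ_g(φ) − ½ log det(Xᵀ W_g X) ]` on a log-spaced grid over
   [1e-4, 10] (21 points) with bounded scalar refinement between the best
   grid point's neighbours. If the optimum sits at the lower bound and the
   Poisson fit's mean Pearson χ² per residual degree of freedom is ≤ 1, the
   estimate is 0 (Poisson). No tagwise/empirical-Bayes shrinkage is
   attempted — a deliberate simplification; the package does not aim to
   replicate edgeR's per-gene numbers, only the analysis structure.
3. **NB GLM + LRT.** Design `~ 1 + diet + treatment` with offsets
   `log(library size × TMM factor)`; the tested factor is dropped for the
   reduced model and the other kept as covariate. Fitting is IRLS with log
   link and weights `μ/(1+φμ)`, vectorized over genes (one batched solve per
   iteration), with step-halving on likelihood decreases, linear-predictor
   clipping at ±30, convergence when the relative log-likelihood change
   falls below 1e-8, and a 100-iteration cap; non-converged genes get NA
   p-values and are excluded from the FDR denominator. LRT statistic
   `2(ℓ_full − ℓ_reduced)` against χ²(1); logFC is the contrast coefficient
   divided by ln 2 (log2 scale). At φ = 0 the fit reduces to the Poisson
   limit and matches a direct per-group likelihood maximization to ~1e-10.
4. **FDR.** Benjamini–Hochberg step-up (via statsmodels), NA-aware; the DE
   cutoff is *strict* FDR < 0.2 — a deliberately lenient threshold whose
   purpose is downstream trend analysis (clustering, correlation), not
   individual discovery claims.

Calibration, verified in the test suite: pooled type-I error at p < 0.05 is
0.05 ± 0.02 under a null NB simulation (φ = 0.1, 6+6 samples, 500 genes, 200
replicates), and planted |log2FC| = 2 at mean count ~100 is recovered with
sensitivity ≥ 0.8 at the 0.2 cutoff.

## Polarization enrichment

The M1/M2 set maps miRNA names to a polarization label (M2a/M2c collapsed
into M2). Name matching strips species prefixes (rno-/mmu-/hsa-) and case,
because labels derived from mouse data are applied to rat identifiers.
Enrichment is the one-sided (greater) hypergeometric tail
`p = P[X ≥ k]`, `X ~ Hypergeom(N, K, n)` with k = overlap, K = labelled
miRNAs in the universe, n = DE miRNAs, N = universe size. The universe is
the set of miRNAs that passed the expression filter (the tested set) and is
a required input, never defaulted. The tail is evaluated by scipy's
log-space survival function and is tested against exact rational enumeration
for all N ≤ 12 tables. The odds ratio uses a 0.5 continuity correction when
any 2×2 cell is zero. One-sided "greater" was chosen because the scientific
claim is enrichment; the test is monotone in k by construction.

## Co-expression

Pearson r for all pairs of retained miRNAs (zero-variance rows dropped with
a warning), two-sided p from `t = r√((n−2)/(1−r²))` with n−2 df; the matrix
is explicitly symmetrized (floating-point BLAS output is not bitwise
symmetric) and clipped to [−1, 1]. Expression scale: TPM of baseline samples
for the sequencing arm; log2 relative expression for the qPCR arm.

Significance is a **conjunction**: r beyond the empirical `tail_fraction`
(default 2.5%) upper or lower quantile of all off-diagonal correlations
*and* p < α (default 0.05). Quantiles use numpy's linear order-statistic
interpolation — stated because tail thresholds depend on the definition.
Positive and negative significant pairs both count as significant.

Per-cluster enrichment: a 2×2 table of (within-cluster pairs vs all other
pairs) × (significant vs not), one-sided Fisher, one test per cluster;
clusters with < 2 retained members are skipped with a note. The background
includes pairs inside other clusters — the simplest reading — and per-pair
strata are recomputed per cluster, so the choice is easy to change.
Cross-cluster summaries (mean r, fraction significant, dominant sign over
all between-cluster pairs) cover the anti-correlation analyses.

## qPCR (ΔΔCt)

Replicate Ct values are arithmetically averaged per (sample, target).
`ΔCt = mean Ct(target) − mean Ct(reference)` (18S for mRNA assays, SNORD68
for miRNA assays, or whatever the table records); `ΔΔCt = ΔCt − mean ΔCt` of
the control group; relative expression `2^(−ΔΔCt)`. The control group's
geometric mean is exactly 1 per target, and the result is invariant to
adding any constant to all Ct values of a sample. Ct values must lie in
(0, 45).

Group comparison is a two-sided Welch t-test on log2 relative expression
(equivalently −ΔΔCt). The original analysis used a SAS general linear model
with least-square means and Shapiro–Wilk-gated log transformation; here the
gate is collapsed to "always analyse on the log scale", where fold data are
closest to normal, and the Welch test drops the equal-variance assumption.
Per-target published p-values are therefore not reproduction targets; the
test's type-I calibration is verified by simulation instead.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with ground truth:

* **Annotation:** `n_clusters` (default 13) clusters of 4–10 members (arm
  pairs named −5p/−3p), spans ≤ 60 kb, placed ≥ 2 Mb apart and ≥ 2 Mb from
  any of the `n_solitary_mirnas` (default 60) solitary miRNAs — the spacing
  makes cluster truth unambiguous regardless of window semantics. Host genes
  (sense/antisense/none) are emitted per cluster in rotation.
* **Counts:** NB(μ, φ) with φ = 0.1 by default; per-miRNA baselines
  log-normal (log mean = log 200, sd 1.2); 5% all-zero rows to exercise the
  expression filter; a 2×2 pair/ethanol × baseline/LPS design with 3 samples
  per cell (6 baseline samples, matching the study); 10% of miRNAs carry a
  diet effect of |log2FC| = 2, 95% of them down (the study found 38/40
  down); the LPS effect defaults to 0 (the study found none); library-size
  offsets log-normal (sd 0.1).
* **Latent-factor correlation:** for each co-regulated cluster c (default:
  3 of 13) and sample j, a shared normal factor z_cj is added to member i's
  log mean with loading `λ_i = sqrt(ρ·v_i/(1−ρ))`, where
  `v_i = 1/μ_i + φ` is the delta-method variance of the log count. This
  makes the log-scale within-cluster correlation ≈ ρ (default 0.9)
  analytically; a Monte-Carlo test confirms mean within-cluster log-TPM
  correlation in [0.8, 0.95] at 50 samples. The approximation degrades for
  very low-mean members and, when cluster members dominate the library, TPM
  normalization itself absorbs part of the shared factor — the calibration
  test therefore uses an annotation with 200 solitary miRNAs, the realistic
  regime where cluster members are a small library fraction.
* **Polarization labels:** `n_polarization` (default 20) miRNAs are
  labelled, a configurable fraction (default 0.5) drawn from the true-DE
  set, so enrichment is planted by construction.
* **Ct tables:** `Ct(target) = baseline − log2(expression) + N(0, σ)` with
  σ = 0.5 cycles, constant reference gene, healthy n = 9 vs AH n = 10
  (the study's group sizes), planted 4-fold AH effects in 3 of 8 targets,
  and latent-factor-correlated target pairs (ρ = 0.9).

Identical seed + config gives byte-identical outputs; all randomness flows
through `numpy.random.default_rng(seed)` streams derived from the single
config seed.

**What the generator does not emulate:** read-level noise and mapping
artefacts (counts are drawn directly, not aligned), tagwise dispersion
heterogeneity, GC/length biases, correlated library composition beyond the
planted factors, amplification-efficiency variation in qPCR, and patient
covariates. Tests passing on synthetic data therefore demonstrate the
correctness and calibration of the *methods* under the assumed model, not
robustness to every artefact of real sequencing data.

## Reproduction fixtures and their limits

The packaged cluster-coordinate table transcribes the published 13-cluster
table; member coordinates are interpolated inside each printed span (span
endpoints exact, interior positions synthetic), which is immaterial to any
span-based cluster call. Two mature miRNAs occur in two clusters each
(miR-181a-5p, miR-181b-5p, from distinct loci); the second occurrence gets a
`.2` suffix to keep names unique. The full 44-entry polarization set and the
complete DE table are not redistributable in full; the packaged versions are
synthetic stand-ins (marked in filename and header) that preserve the
published structure — the 9 published polarization rows with their printed
logFC/FDR, 40 miRNAs at FDR < 0.2 (2 up, 38 down), 23 of them cluster
members. Checks that require the deposited sequencing data (GEO GSE95403)
live in `scripts/reproduce_accession.py` and are not part of the test suite.

## Problem sizes used in simulation tests

Null calibration uses 200 replicates of 500 genes (6+6 samples); DE recovery
500 miRNAs; co-expression recovery 50 seeds of 6 clusters + 40 solitary
miRNAs at 20 baseline samples — 20 rather than 6 because detecting ρ = 0.9
through empirical 2.5% tails needs the sampling spread of r (≈ 1/√(n−3) on
the Fisher z scale) to be well below the gap between ρ and the null tail
quantile; at n = 6 a true-ρ pair regularly falls below the threshold, so the
recovery property is a statement about the method at adequate sample size,
not about 6-sample power. The qPCR null calibration uses 1000 replicate
targets at the study's group sizes.

## Known limitations

* Common dispersion only; genes with atypical dispersion get miscalibrated
  per-gene p-values (the FDR-0.2 trend-analysis use case tolerates this).
* The greedy span chaining is order-deterministic but, like any 1-D
  chaining, can split a dense run that a different anchoring would join;
  with the ≥ 2 Mb spacing of real and simulated clusters this never occurs.
* Host-relation classification uses simple interval logic on `gene`
  features; it does not check intron boundaries, so "sense-intronic" means
  "contained in a same-strand gene".
* Correlation significance combines an empirical-tail cut with a parametric
  p-value; with few samples the parametric p dominates, with many samples
  the tail cut does. This mirrors the published procedure but means the
  effective stringency depends on sample size.
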