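# Methods

This note documents the statistical models implemented in
`statewise-burden`, the synthetic cohort generator that the test suite
exercises them on, and the numerical and design choices a maintainer would
want to know about.

## The analysis problem

Whole-genome case-control studies of rare and low-frequency variation often
enlarge their control group with externally sequenced, unscreened samples.
Even after joint genotype calling, the two control sources differ in
sequencing depth and library chemistry, and those technical differences
perturb exactly the variants that rare-variant aggregation tests are built
from. The package implements the full diagnostic and testing battery for
this situation:

* **Category burden tests** — for each genome annotation category *c*
  (chromatin/conservation state, repeat class, gene, gene set) and sample
  *s*, the predictor is the weighted non-reference allele count
  `B_sc = Σ_{v∈c} w(MAF_v) · g_sv`, with Beta(1, 25) weights
  `w(f) = 25 (1−f)^24` that upweight the rarest variants. Case/control (or
  cohort) status is regressed on `B_sc` by logistic regression, adjusting
  for 10 genetic PCs, sex, sequencing batch (internal-only comparisons),
  the per-sample total weighted burden, and — in the `base+metaPCs` model —
  the first four sequencing-metadata PCs.
* **Genomic-control diagnostics** — for a family of category p-values,
  `λ_GC = median(Q_χ²₁(1−p)) / 0.45494`. A calibrated family sits near 1;
  uncorrected cross-cohort calling differences inflate it.
* **Single-variant scan** — covariate-adjusted logistic association per
  variant with minor allele count > 20, λ_GC over all tested variants.
* **Sliding-window scan** — Beta(1,25)-weighted burden tests in 5–50 kb
  windows stepping by half their size, with an effective number of tests
  estimated from the permutation distribution of the scan's minimum
  p-value.
* **Singleton-PTV gene tests** — unweighted counts of singleton
  protein-truncating alleles per gene (singletons defined on the unrelated
  sample set), tested for genes with more than 10 singletons, plus summed
  gene-set tests and a MAF ≤ 1% sensitivity mode.
* **Analytic power** — non-centrality of the 1-df allele-dosage trend test
  under a multiplicative disease model, with a bisection solver for the
  detectable odds ratio at 80% power.

## Logistic engines

`burden_logistic_test` fits the full maximum-likelihood model and reports a
two-sided Wald p-value on the burden coefficient. Separation or
non-convergence (plausible for rare burdens with unbalanced outcomes)
triggers a Firth (Jeffreys-prior) penalised refit, flagged in the result.
Genome-wide scans (GWAS, windows, and optionally the 200-category state
scan) instead fit the covariate-only null once and apply Rao score tests to
every column; under the null the score and Wald statistics are
asymptotically identical (the test suite asserts their agreement), and the
scan reduces to a handful of matrix products. For score results the
reported coefficient is the one-step Newton approximation U/V.

Windows with fewer than three analysed variants are not tested. A one- or
two-variant burden is close to a Bernoulli predictor; its score/Wald
p-value distribution is visibly non-uniform and, when covariates predict
the outcome strongly (metadata PCs in a two-cohort comparison), the scan's
λ_GC drops to ~0.7 purely from discreteness. With ≥3 variants per window
the null scan is calibrated in both covariate models.

The effective-number-of-tests estimator permutes outcome labels within
deciles of the fitted null linear predictor — plain permutation would break
the covariate-outcome association and overstate the number of independent
tests — and reuses the unpermuted null weights, so each permutation costs
one matrix-vector product. The minimum p over the scan is fit by maximum
likelihood to Beta(1, n): `n̂ = −R / Σᵢ log(1 − p_min,i)` over R
permutations, and the scan threshold is 0.05/n̂. Family-wise error control
of this threshold is verified empirically in the test suite.

## Power model

Genotype penetrances are multiplicative on the baseline risk,
`f_g = f₀ · OR^g` under HWE, with `f₀` solved by log-space bisection so the
population prevalence equals K; controls are population-based (unscreened),
cases follow the disease-conditional genotype law. Under this
parameterisation the case risk-allele frequency is exactly
`p·OR / (1 − p + p·OR)`. An odds-scale alternative (`odds_g = odds₀·OR^g`),
which saturates for highly penetrant genotypes, is available via
`scale="odds"`. Power is the upper tail of the non-central χ²₁ at the
central (1−α) quantile, with the NCP given by the Cochran-Armitage trend
statistic evaluated at expected counts (an allelic 2×2 mode is provided for
sensitivity). A Monte-Carlo test validates the analytic power against
simulated genotype tables.

## Synthetic cohort generator

The generator is first-class, tested code; it produces the statistical
structure the analysis assumes, with every latent quantity recorded in a
truth record so recovery tests never peek at internals.

* **Samples** — four groups (BD cases, SZ cases, internal controls,
  external controls), default 600/1,200/900/3,300 — a ~0.39× scaled image
  of the study-like unrelated group sizes. Sex is Bernoulli per cohort
  (42% female internal, 62% external). Internal samples carry one of three
  batch labels, external samples one.
* **Genome and annotations** — default 2 chromosomes × 250 Mb carrying
  50,000 SNVs. The genome is tiled into 10-kb segments, each assigned one
  of 200 annotation states; a prefix of each segment is covered by a repeat
  interval. Each state has a log-normal repeat *affinity* (sd 1.3) scaling
  how much of its segments are repeat-covered (genome-wide fraction 0.5),
  and its own Dirichlet-drawn repeat-*class* composition (concentration
  0.3 around genome-wide class weights, 21 classes + "overall"), so states
  differ both in how much repeat they contain and in which families —
  the coupling that makes state-level tests sensitive to repeat-class
  calling artifacts. The genome is deliberately long and sparse: a state
  aggregates ~250 variants while a 50-kb window holds ~5, reproducing the
  WGS-scale contrast in which category tests feel calling artifacts that
  window and single-variant tests cannot resolve. Genes are 1,000 evenly
  spaced intervals (PTV flag rate 0.10 inside genes); ~1% of the genome is
  flagged as excluded regions.
* **Allele frequencies** — ancestral MAFs from Beta(0.2, 6) truncated to
  [1/(2N), 0.5] by inverse-CDF sampling; two ancestral components diverged
  by Balding-Nichols with Fst = 0.003; per-sample admixture Beta(8, 2).
  The gradient is strong enough that PC1 separates ancestry but weak
  enough that ten common-variant PCs fully absorb rare-variant
  stratification (at Fst 0.01 the pure-null state-scan λ_GC centres at
  ~1.07; at 0.003 it centres at 1.000).
* **Disease models** — prevalences 1% (BD), 1% (SZ), 2% (SZ+BD).
  `assign_phenotypes` implements the prospective logistic model
  (intercept solved by bisection to match prevalence). `generate_cohort`
  fills fixed case quotas retrospectively: at variants inside a configured
  effect region, case allele frequencies are tilted to
  `p·e^β/(1−p+p·e^β)`, the first-order case-conditional law of the
  logistic model — simulating prospectively at 1% prevalence would need
  ~100× the genotypes.
* **Sequencing depth and differential calling** — internal depth
  N(26.8, 5.5), external N(36.8, 4.7). Dropout (1→0) probability falls
  with depth, `floor + (ceil−floor)·σ(−(depth−30)/5)`, ceiling 0.045,
  applied to all rare variants (MAF < 0.05); spurious calls (0→1) rise
  with depth, ceiling 5×10⁻⁴, restricted to ultra-rare sites
  (MAF < 0.002). Both are scaled by repeat-class multipliers (SINE 4,
  simple repeat 3, LINE/LTR 1.5, other repeats 1.5, non-repeat 0.05).
  The split is the key design point: dropout is multiplicative in carrier
  count, so it shifts no single tested variant materially (GWAS λ stays
  ~1.01) yet accumulates over the hundreds of variants a state aggregates
  (control-control state λ ~1.5 without metadata PCs); additive spurious
  calls at that strength would inflate the single-variant scan, which is
  not the observed real-data pattern. Rates were calibrated once so the
  default two-cohort comparison reproduces the
  inflated-then-corrected λ pattern, and then frozen.
* **QC metrics** — seven per-sample metrics generated as depth-driven
  functions plus noise: mean depth, contamination (independent noise),
  fraction of sites ≥10× and ≥30×, Q20 base fraction, callable fraction,
  coverage uniformity. The ≥30× completeness is a steep threshold-like
  probit in depth whose shape closely matches the logistic depth link of
  the calling model, so the four metadata PCs span the corrupting signal.
* **Relatedness** — duplicates copy genotype rows before the calling noise
  (each copy then receives independent noise); offspring inherit one
  transmitted allele per variant from the parent plus one population
  draw.

What the generator does **not** emulate: linkage disequilibrium beyond the
shared ancestry gradient (variants are conditionally independent), X
chromosome hemizygosity (autosomes only), realistic gene length/PTV
distributions, genotype-quality scores, and sequencing-read-level error
processes. Passing tests therefore demonstrate that the statistical
machinery behaves correctly under the assumed data-generating structure —
calibrated nulls, recoverable injected effects, batch-effect signatures of
the documented shape — not that any specific real-data finding would
replicate.

## Sample QC

Hard filters: contamination > 5%, < 98% of sites at depth ≥ 10, or
reported/genetic sex mismatch. Kinship is the KING-robust within-pair
estimator `φ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa,i + N_Aa,j)` on common
variants (MAF > 5%), computed via three indicator-matrix products and
capped at 12,000 subsampled variants (null φ SD ≈ 0.008, putting the
0.0409 third-degree threshold > 5σ from zero). Relatedness pruning resolves
duplicate pairs (φ > 0.354) first with internal-over-external priority,
then removes the highest-degree sample of the φ > 0.0409 graph
(seeded-random tie-break) until no edge remains — on a chain A–B–C this
keeps A and C; the retained set is verified against an all-pairs check.
LD pruning walks variants in position order and drops any variant with
r² > 0.2 against a retained variant within 500 kb upstream; genetic PCs
are Lanczos singular vectors of the centred, variance-standardised dosage
matrix with the sign fixed by the largest-magnitude loading.

## Numerical choices

* Missing genotypes (≤ 0.1% in synthetic data) count as homozygous
  reference in burden construction and are excluded from MAC for
  single-variant tests.
* MAF/MAC are recomputed on each comparison's sample set; the minor allele
  may be the reference allele, and `w(MAF)` always takes the minor-allele
  frequency while the summed count remains the non-reference count.
* λ_GC clips p = 0 to the smallest positive double and flags it.
* Two-sided Fisher exact p sums hypergeometric point probabilities
  ≤ observed × (1 + 10⁻⁷) (minimum-likelihood convention).
* The Firth fit damps Newton steps to at most 5 per coordinate and reports
  Wald intervals from the penalised information.
* Degenerate inputs (constant burden, empty category, zero-heterozygote
  kinship pair) are flagged, never silently dropped.

## Problem sizes used by the test suite

The acceptance-style tests run the generator at its default scale for the
two-cohort λ-pattern scenario, pooling category p-values over eight seeded
cohorts before computing λ_GC, because the median-based λ over 200 tests
has a sampling SD of ≈ 0.165 — single-run λ bounds tighter than ±0.16
would fail a perfect null about half the time. Repeat-class recovery runs
50 replicates at 3,000 samples × 8,000 variants; window recovery runs 20
replicates on a dense 2-Mb genome (6,000 variants) so a 10-kb window holds
~25 rare SNVs; the effective-tests check uses 50 disjoint windows with
3,000 permutations. The Monte-Carlo power validation uses 50,000 simulated
tables at α = 10⁻³.

## Known limitations

* The score-scan permutation reuses plug-in null weights; for extremely
  unbalanced outcomes the min-p calibration degrades (tested bands allow
  ±30% on n_eff).
* Without LD, the LD-pruning and PC stages are exercised only against
  duplicated-column and two-population structure, not realistic haplotype
  structure.
* The mixed-model + saddlepoint machinery of large-scale GWAS tools is
  deliberately replaced by logistic tests on the pruned unrelated set;
  residual cryptic relatedness beyond the pruning threshold is not
  modelled.
* Windows below three analysed variants are untested by design; on sparse
  genomes this removes most 5-kb windows.
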