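# Methods

This note records the statistical model, the parameter conventions and the
numerical methods used by `cnvburden`, together with known limitations.

## Study design

The package analyses a case-control study of rare CNVs across several
genotyping cohorts.  Each sample carries zero or more autosomal CNV calls
(gain or loss, with a probe-support count); each call is annotated against
a gene model and a catalogue of gene sets.  Inference is carrier-based
throughout: a sample either carries ≥1 qualifying call or it does not, so
multiple calls in one sample never inflate a test.

## Quality control

Calls pass a fixed five-stage chain, in order:

1. **Size** — keep calls strictly larger than `min_size_bp`
   (default 100,000 bp).
2. **Probe support** — keep calls with `n_probes ≥` the per-cohort
   threshold (default 50; array platforms with denser probes can demand
   100).
3. **Blacklist** — remove calls overlapping a problematic-region BED by
   ≥1 bp.
4. **Outlier samples** — per cohort, exclude samples whose call count
   exceeds the cohort mean plus `outlier_sd` (default 3) population
   standard deviations of the per-sample counts; a single upper-tail pass.
5. **Rarity** — cluster calls of the same type by single-linkage at
   ≥ `reciprocal_overlap` (default 50%) reciprocal overlap; remove
   clusters whose carrier frequency among retained samples is strictly
   greater than `max_frequency` (default 1%).

Stage counts are reported after every step; the chain is idempotent.

## Gene-set burden

For each cohort and gene set (plus the "any CNV" pseudo-set), a 2×2 table
of carrier status × case status is tested two-sided.  Per cohort,
9 hypotheses (any + 8 sets) give a Bonferroni threshold of
0.05/9 (displayed truncated as 0.0055); gain-only and loss-only strata are
reported at the nominal 0.05.

### Exact 2×2 inference

* **p-value**: conditional on both margins, the sum of noncentral
  hypergeometric probabilities at odds ratio 1 that do not exceed the
  observed probability, with a relative tie guard of 1 + 1e-7 to make the
  discrete comparison robust to floating-point noise.
* **Odds ratio**: conditional maximum-likelihood estimate — the odds
  ratio whose noncentral hypergeometric mean equals the observed cell;
  0 or ∞ at the support boundary, undefined (NaN) when the margins fix
  the table.
* **Confidence interval**: exact, by inverting the one-sided tail
  probabilities at 0.025 each.

Scalar root-finding uses Brent's method (`xtol=1e-14`, machine-precision
`rtol`).  A vectorised batch path computes log-weights via `gammaln`, the
CMLE by damped Newton iteration in log-odds (40 iterations, step clipped
to ±4) and the CI tails by bisection (72 iterations over log-odds ∈
[−80, 80]), chunked at 100,000 tables.  Batch and scalar paths agree to
~4×10⁻¹⁴ and both agree with an independent exact-integer enumeration
oracle to better than 10⁻¹² over every table with N ≤ 60.

## Covariate-adjusted association

Fifteen binomial logistic models: carrier predictor ∈ {any CNV, lipid,
small intestine, lipid ∩ small intestine, small intestine ∖ lipid} ×
stratum ∈ {all, women, men}.  Covariates: age, BMI, dataset indicators
(largest cohort as reference) and, in unstratified models, sex coded
male = 1.  Fitting is Newton maximum likelihood (tolerance 1e-8, ≤100
iterations) with Wald z inference and 95% intervals on the exp scale.
Strata with <10 cases or <10 controls are rejected; exactly collinear
columns are pruned by rank checks; (quasi-)complete separation — a
singular Hessian, or |estimate| > 15 on a binary predictor — is flagged
as non-converged rather than reported as trustworthy (the Hessian case
falls back to a BFGS fit so the grid can continue).  The familywise
threshold is 0.05/15 (displayed 0.0033).

## Candidate genes

A four-stage deterministic filter: lipid-set genes → also in the tissue
(small-intestine) expression set → overlapped by ≥1 retained case call →
overlapped by no control call in any cohort.  Enrichment of a k-gene hit
among the eligible genes can be scored with an exact hypergeometric tail.

## Synthetic cohorts

The generator builds, from a single seed (via `SeedSequence` spawning, so
every component stream is independent and reproducible):

* a gene model of 4,400 non-overlapping 50 kb genes over 22 autosomes,
  with 8 gene sets whose sizes scale a ~20,000-gene catalogue by 0.22
  (lipid 343, small intestine 841, overlap 81, …) and a 20-region
  blacklist placed outside genes;
* three cohorts matching the default study table (1,957 + 1,745 + 1,076
  samples; deterministic sex counts, e.g. exactly 40 male cases in the
  third cohort at 92.3% women; truncated-normal age and BMI);
* Poisson per-sample call counts at the configured rates (0.42–0.88
  calls/sample), call sizes log-uniform on (100 kb, 3 Mb], gains with
  probability 0.742, positions uniform outside the blacklist.

Effect injection targets a chosen odds ratio for a chosen set in a chosen
sex × status stratum.  The baseline carrier probability
q = 1 − exp(−rate·p̄) is computed analytically (p̄ is the mean
per-call set-hit probability, from the exact interval union of set genes
and 96-node Gauss–Legendre quadrature over log call size); the extra
carrier probability is p = (p₁ − q)/(1 − q) with
p₁ = OR·q / (1 − q + OR·q), so the realised crude odds ratio is unbiased
for the target.

**Generator limits**: calls are independent within samples, with no
genomic hotspots, linkage structure or platform batch artefacts; covariate
distributions are truncated normals without case-control confounding
beyond their configured means.  These are deliberate simplifications —
the generator exists to calibrate and test the inference machinery, not
to emulate biology.

## Known statistical limitations

* Fisher's exact test is conservative for discrete tables: at the carrier
  frequencies and cohort sizes produced by the default configuration its
  measured size is ≈0.040–0.047 at nominal 0.05.  Raw rejection rates
  pooled across many null replicates therefore fall at or below the lower
  edge of a tight binomial band centred on 0.05; this is a property of the
  exact test, not an implementation defect.
* Wald intervals from the logistic models are asymptotic; with very few
  carriers in a stratum they can under-cover, and separation is flagged
  rather than resolved (no penalised likelihood).
* Bonferroni control is applied per pre-registered family (9 burden
  hypotheses per cohort; 15 grid models); type-stratified burden tests
  are exploratory and only nominally controlled.
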