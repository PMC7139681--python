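# Methods

## Model and estimands

The exposure is genetically predicted leukocyte telomere length,
proxied by a weighted allele score over 11 instrument SNPs:
`GRS_i = Σ_j w_j x_ij`, with `x_ij` the long-allele dosage and `w_j`
the SNP's published per-allele LTL effect (all weights harmonized
positive toward the long allele; their sum is 0.811, so scores live in
`[0, 1.622]`). The outcome model is unconditional logistic regression
of case status on the score's category indicators, adjusted for age
(years, untransformed) and sex (indicator, female = 1). This is the
standard one-sample GRS formulation of Mendelian randomization; it
assumes the instruments affect disease only through the proxied trait
and are independent of confounders. No ratio-of-coefficients or
two-sample MR estimator (IVW, Egger) is computed — the estimand is the
category-level odds ratio itself.

Three categorization schemes are reported: dichotomized at the control
median, tertiles, and quartiles of the control distribution. Cutpoints
are **always** computed from the full control group and reused
unchanged in stratified analyses, so every stratum shares one
Short/Long split; within-stratum re-derivation would change the
estimand from "long versus short on the cohort's scale" to something
stratum-relative.

## Statistics engine

Logistic models are fitted by Newton–Raphson (equivalently IRLS) with
convergence at max |score| < 1e-8 or |Δdeviance| < 1e-10, capped at 50
iterations; standard errors come from the inverse observed information
at the optimum, and all intervals and p-values are Wald
(z₀.₉₇₅ = 1.959964). These tolerances are fixed constants so reruns
are bit-identical. Separation (fitted probabilities pinned at 0/1 with
diverging coefficients) and rank-deficient designs raise explicit
errors naming the problem; per-SNP stage failures flag the row and
continue.

Supporting 2×2 machinery: crude OR `ad/bc` with the Woolf SE
`sqrt(Σ 1/cell)` and a Haldane–Anscombe +0.5 correction (flagged) when
a cell is zero; Pearson χ² `(ad−bc)²·N / (margin product)` with the
Yates correction available but off by default; Fisher's exact test by
full hypergeometric enumeration using the point-probability rule (sum
of all tables with probability ≤ observed, with a 1e-7 relative
tolerance for floating-point ties), capped at N = 100 000 before the
caller is told to use χ². The trend test enters the 1..k category
index as a single ordinal numeric term in the adjusted logistic model
and reports its Wald p — the most common epidemiological convention —
with a covariate-free Cochran–Armitage variant exposed as an
alternative.

## Harmonization and missingness

VCF sites are matched on (chrom, pos) with allele verification, rsID
as fallback (imputed files often lack IDs). If REF/ALT do not match
the instrument's allele pair directly, the default mode retries on the
reverse-complemented strand; palindromic (A/T, C/G) instruments are
never auto-flipped because strand cannot be resolved, and a strict
mode turns every flip into an error. None of the 11 packaged
instruments is palindromic, so the default is safe for the shipped
table. Hard GT calls are the default dosage source; the DS field is
available by flag for imputed data — which representation is "right"
depends on the upstream imputation and is left to the caller.

Missing genotypes are mean-imputed per SNP from the control-group
mean, keeping n constant across analyses; a SNP missing in more than
10% of subjects is dropped with a warning instead. Quantile cutpoints
use linear interpolation between order statistics (type 7, the numpy/R
default). A score exactly at a cutpoint goes to the lower ("shorter")
category — intervals are `(cut_{k−1}, cut_k]` — with the opposite rule
available via a switch; with continuous scores the tie mass is
negligible either way.

## Synthetic cohort generator

The generator draws genotypes per SNP as two independent
Bernoulli(EAF) alleles (Hardy–Weinberg, no LD — the instruments are
chosen to be independent), builds the latent trait as the weighted
score plus N(0, σ²) noise, and assigns disease by
`logit P(case) = α + log(OR_true) · Z`, where `Z` is either the
above-population-median indicator of the score (default, mapping 1:1
onto the dichotomized estimand) or the mean-centered continuous score.
`α = logit(baseline prevalence)` makes the null-exposure group sit
exactly at the baseline prevalence (default 0.05 — the disease is
rare, so odds ratios approximate risk ratios and stay interpretable).
Cases and controls are then sampled without replacement from the
population, which auto-doubles (hard cap 2 × 10⁶ subjects) until both
arms are attainable.

Default conditions: arms of 821 cases / 851 controls; case ages
N(56.39, 11.58²), control ages N(57.00, 8.62²), truncated at 18;
52.7% female in both arms; subtype shares Leiomyosarcoma 0.331, GIST
0.268, Liposarcoma 0.220, Angiosarcoma 0.073, Other 0.107 (a single
forced subtype is available for stratum-specific studies). The noise
SD defaults to the value making the score explain 2% of latent-trait
variance — `Var(GRS) = Σ β²·2p(1−p) = 0.0233` under HWE, giving
σ ≈ 1.068; the trait's absolute units are arbitrary, only this
variance share is calibrated. Age and sex are simulated independent of
genotype: the generator reproduces the *no-confounding* MR assumption,
so passing recovery tests demonstrate estimator correctness under the
model, not robustness to population stratification, LD, genotyping
error, or genotype-correlated demographics, none of which are
emulated. Each cohort uses a single fixed RNG stream from its seed;
replicate r of a calibration study uses seed + r.

## Calibration studies and problem sizes

`pipeline.dichotomized_recovery` is the package's calibration harness:
simulate replicates with a known dichotomized log-OR, re-estimate with
the reporting pipeline's adjusted model, return per-replicate
estimates and SEs. The shipped acceptance script runs it at 200
replicates for two designs — 821/851 with true OR 1.44, and a
200-case subtype stratum against 851 shared controls with true OR
2.20, analyzed through the subtype-stratified stage. Two hundred
replicates put the Monte-Carlo SE of the mean log-OR near 0.007
(overall design), small against the 0.05 acceptance band used in the
tests. A mild attenuation (~1–2% on the OR) is expected in the
stratified design because cutpoints come from the sampled controls
rather than the source population; it stays well inside the stochastic
tolerance.

The test suite's simulation sizes (40–200 replicates of cohorts
between 120 and 1700 subjects, 500 small replicates for the trend
test's null calibration) were chosen so Monte-Carlo error is a small
fraction of each asserted band while the full suite stays quick to
run.

## Known limitations

* One-sample, category-level design only: no IVW/Egger two-sample
  estimators, no per-SD continuous-score analysis, no conditional
  logistic regression (controls are frequency-matched, not paired).
* No multiple-testing adjustment — per-SNP p-values are nominal.
* The subtype stage compares each subtype's cases against the full
  control set; subtypes are not mutually adjusted.
* Multi-allelic VCF records are rejected rather than decomposed;
  upstream normalization is expected.
* The generator's rare-disease sampling makes control allele
  frequencies track the population values; it is not a model of
  ascertainment bias.
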