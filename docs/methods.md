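# Methods

This note documents the models, conventions and numerical choices behind
`wgsburden`, and what the synthetic-data tests do and do not establish about
real cohorts.

## The analysis model

The unit of inference is a per-sample count of qualifying variants in a
named annotation. An ultra-rare variant (URV) is a cohort singleton
(allele count exactly 1, heterozygous in exactly one subject) with allele
count 0 in every external population reference; an ultra-rare SV is a
single-occurrence call that no same-type database SV overlaps by ≥ 30% of
the call's length. SNV/indels count toward an annotation when their position
falls inside it; SVs count when they cover at least 10% of at least one
annotation element (the element's length is the denominator; the SV-length
reading is available via `denominator="sv"` — the choice matters for large
SVs against small elements and is deliberately configurable because the
convention is not standardised).

Burden tests are logistic regressions

    phenotype ~ covariates (+ genome-wide count) + target count

with the odds ratio per unit count, one-sided Wald p for a case excess, and
an empirical p from phenotype-label permutations. The permutation statistic
is the Wald z (not the p), so that non-convergent refits can be counted
conservatively as at-least-as-extreme; the estimator is
(1 + #{z_perm ≥ z_obs}) / (n_perm + 1), which cannot return 0. Covariates
stay attached to samples during permutation (only labels swap); this matches
the usual label-swap phrasing but breaks any phenotype–covariate linkage
under the null — a conservative choice when covariates are confounders.
Covariate selection is itself empirical: each PC is screened as a sole
logistic predictor of phenotype (two-sided p < 0.01), and for SV models the
PCs are screened jointly in a linear model for the genome-wide SV count
(p < 0.05). BH-FDR is applied within declared test families (the two
families in the motivating study hold 74 SNV/indel tests and 29 SV tests;
family membership is run configuration, not code).

The logistic solver is an in-package IRLS/Newton iteration with
step-halving, convergence at gradient norm < 1e-8, a 100-iteration cap, and
separation flagged when any coefficient passes |β| > 20. It exists because
permutation nulls and the type-I-error acceptance run perform ~10⁵ refits;
statsmodels is used as an independent cross-check in the tests, never as the
production path for these fits. The vectorised single-variant scan runs the
same Newton iteration batched across variants (additive 0/1/2 dosage,
two-sided Wald p, MAF > 0.01), and λ_GC is median(χ²₁)/0.4549.

## Quality control conventions

- Genotypes with DP < 10 or GQ < 20 are set missing (boundaries inclusive
  on the keep side).
- Variant filters, in order: monomorphic; missing rate > 0.02; case/control
  missing-rate difference > 0.02 or two-sided Fisher p < 0.005 on the
  called/missing × case/control table (the test is unspecified in the
  motivating study; Fisher is the conservative default); Hardy–Weinberg
  exact-test BH-FDR below 1e-6 in controls or 1e-10 in cases, adjusted
  within each phenotype stratum across all variants entering the filter.
  The chain is idempotent (BH adjusted values only grow when smaller
  p-values leave the family).
- The HWE test is the standard exact conditional test (probability-mass
  two-sided, not mid-p), computed from log-gamma terms over all heterozygote
  counts compatible with the allele-count margins. The test suite checks it
  to 1e-12 against an independent enumeration, exhaustively for n ≤ 25.
- Relatedness: π̂ is the method-of-moments relationship coefficient from
  standardized genotypes on common variants (MAF ≥ 0.05), i.e. the GRM
  entry; self values sit near 1 + F, duplicates near 1, parent–child near
  0.5. Allele frequencies are estimated in-sample, which biases π̂ for a
  related pair downward by O(k/n) (k relatives, n samples) — negligible at
  cohort scale, visible in 20-sample toys. Pruning removes, repeatedly, the
  sample with the most remaining above-threshold pairs, tie-broken by higher
  missingness then lexicographically larger id.
- URV outlier pruning removes samples with counts strictly above the
  threshold (6000 at the study's ~4250 mean); for synthetic cohorts at other
  depths `default_urv_outlier_threshold` scales the same relative excursion,
  mean × (1 + 1.5 × (6000/4250 − 1)).
- SVs are removed when blacklist intervals cover strictly more than 66% of
  their length (union of intersections, so abutting blacklist pieces
  accumulate).

## Power

Expected risk-allele frequencies in cases and controls follow an additive
penetrance model: penetrances proportional to (1, γ, 2γ−1), scaled so the
population risk equals the lifetime prevalence K (1% by default), genotypes
under HWE at the population MAF; the implied homozygote penetrance must not
exceed 1. Power is the one-sided normal test comparing the two expected
frequencies with unpooled variance and **one observation per subject** —
the convention of the genetic power calculators used for study design in
this literature, which treats the group frequency as a per-subject
proportion. This convention is roughly a factor of 2 more conservative in
information than a per-allele (2N-chromosome) test; it is adopted here
because it is what study-scale published design numbers correspond to, and
the package's Monte-Carlo oracle (per-subject Bernoulli draws, same test)
agrees with the analytic formula to ±0.02 across a 5×5 (MAF, γ) grid over
MAF 0.05–0.4. The approximation degrades where expected allele counts are
small: at MAF 0.01 with ~900 cases the analytic power sits ~0.02–0.03 below
an exact binomial evaluation of the same test, a known property of normal
approximations in the deep tail; design numbers quoted at one decimal are
unaffected in the settings used here.
`min_detectable_grr` inverts the power function by bisection to 1e-6 and
returns the attaining side of the root; design numbers are quoted at
one-decimal rounding. The 2×2 helpers use the probability-mass two-sided
Fisher convention (alternatives such as tail-doubling differ in the third
decimal) and the Woolf log-OR interval with a 0.5 continuity correction on
zero cells.

## Heritability

GRM entries are A_jk = mean_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1−p_i))
with residual missingness mean-imputed per variant. LD scores are windowed
sums of r² (10 Mb window by default, self-r² included so scores ≥ 1, no r²
cutoff). The GREML-LDMS partition uses seven MAF bins on boundaries
(0.0007, 0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5], left-open/right-closed with
the floor value included in bin 1 (the first bin's printed range in the
motivating study is a typo for 0.0007–0.001: the floor is 0.0007 and the
second bin starts at 0.001), each split at its own median LD score
(low < median ≤ high; ties all land in high).

REML maximises the restricted likelihood by Fisher scoring (expected
information), convergence at |Δ log-likelihood| < 1e-8 with a 100-iteration
cap, negative components floored at zero, SEs from the inverse expected
information, and the h² SE by the delta method. A single-GRM model is
solved exactly through an eigendecomposition of the GRM (cached on the
GRMatrix object), making iterations O(n); multi-GRM models use dense solves
(O(n³) per iteration), practical to n ≈ 2000 on one CPU. Covariates (plus
an intercept) enter as fixed effects. The observed-scale case/control h² is
converted to the liability scale by K²(1−K)²/(z²P(1−P)) with z the standard
normal density at the threshold Φ⁻¹(1−K); with P = K this reduces to the
unascertained K(1−K)/z² correction.

## What the generator emulates — and does not

Defaults are the study conditions of the motivating cohort: 1162/936
cases/controls; SNV/indel singleton fractions 45.43%/37.03%; ~4250 URVs per
sample with an outlier tail (3.5% of samples at 1.6× by default) standing in
for the ancestry-heterogeneity tail seen in real data; per-type SV counts
17895/4129/4458 (DEL/DUP/INV) with truncated log-normal sizes whose
*truncated* medians equal 2592/7179/3265 bp on 500 bp–1 Mb (μ solved by
bisection; σ = 1.0/1.0/1.2 per type chosen to give the long right tail);
mobile-element sizes on 15 bp–6 kb; lifetime risk K = 1%. Singletons are
heterozygous in exactly one subject. Embedded burden effects place target
URVs (or SVs covering ≥ 10% of a target element) at a case:control Poisson
rate ratio equal to the configured odds ratio, which is exactly the odds
ratio a logistic count model recovers; all other variants are placed outside
the target annotation so the embedding is not diluted. One pseudo-PC (PC1)
is correlated with outlier status and a second (PC2) weakly with phenotype,
so covariate-selection logic has signal to find. All randomness flows from
one seed through named substreams; identical configurations are
byte-identical.

Generator fields beyond the headline knobs (indel fraction 0.12, external
absence fraction 0.90 of singletons, per-genotype QC failure rate 0.002,
2000 embedded target URVs / 200 target SVs, 40-kb TAD bins with 10% flagged
as boundaries, 8 genes/Mb, 2% blacklist) are fixed generator mechanics with
defaults read off the motivating study's descriptive statistics where
available and otherwise set once to values typical of the data type.

Not emulated: haplotype/LD structure (genotypes are HWE draws, so LD scores
on simulated data reflect only chance and block-copy constructions used in
tests), sequencing error models, ancestry structure beyond the single
pseudo-PC, chrX, and mobile-element burden (excluded from rare-SV burden by
design). Passing tests therefore establish the *statistical correctness* of
the pipeline — null calibration, effect recovery, exact-test agreement with
enumeration — not the biological findings of any real cohort, whose
individual-level data are not distributable.

## Problem sizes in the test suite

Tests run the same code paths at desk scale: null-calibration cohorts of
150 samples with ~300 target URVs (500 cohorts for type-I error, 200 for
permutation uniformity at 500 permutations), odds-ratio recovery at
500/500 samples with 2000 target URVs (bands pre-calibrated from 200
independent seeds of the same design, frozen as mean ± 4 SD on the log-OR
scale), a null association scan of 10⁵ variants on 1600 samples, and GREML
at n = 2000, m = 5000 across 20 seeds per simulated h². Full-scale defaults
(millions of singletons) are intended for the statistical structure they
define, not for dense materialisation in memory.

## Known limitations

- The dense multi-GRM REML path scales as O(n³) per iteration; beyond a few
  thousand samples it needs the kind of sparse/streamed machinery dedicated
  tools provide.
- Permutation p-values refit the full model per permutation; at study scale
  with 10,000 permutations this is the dominant cost and is best run with
  the smaller `n_perm` during exploration.
- The per-subject power convention is deliberately conservative (see above);
  analysts wanting per-allele power should halve the implied variance, and
  the Monte-Carlo oracle should be adjusted to match.
- `population_absence` compares within SV type only; databases that merge
  types would need a cross-type option.
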