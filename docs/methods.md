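# Methods

`polypen` studies how polygenic background modifies the penetrance of rare
monogenic risk variants. This note records the models the package
implements, the synthetic data it is validated on, the numerical choices,
and the limits of what the tests demonstrate.

## The analysis model

**Scores.** The raw polygenic score of individual *i* is
`PS_i = sum_v w_v d_iv` over effect-allele dosages `d` in [0, 2] and
per-allele log-odds weights `w`. Because score distributions shift with
genetic ancestry, the analysis uses the residual of an ordinary
least-squares regression of `PS` on the leading ancestry principal
components (default K = 4) as the ancestry-corrected score; this is
standardized by the reference sample's mean and sample (n−1) SD, and mapped
to integer percentiles 1–100 by mid-rank empirical CDF with ceiling
(ties get mean ranks; values outside the reference clamp to 1 or 100).
The reference set defaults to the analysis sample itself; an external
reference distribution can be supplied instead.

**Carriers.** Pathogenicity classification (P/LP/VUS/LB/B) is a clinical
input, never computed. Candidate variants drop synonymous consequences and
variants with allele frequency strictly above 0.005 in at least one
(`mode="any"`, the default) or every (`mode="each"`) reference
subpopulation, then drop low-complexity/segmental-duplication regions and
random-forest-quality failures. A carrier has dosage ≥ 0.9 (≥ 1 for hard
calls; 0.9 tolerates imputed dosages) at at least one surviving P/LP variant
in the condition's genes (FH: LDLR/APOB/PCSK9; HBOC: BRCA1/BRCA2; Lynch:
MLH1/MSH2/MSH6/PMS2). Two qualifying variants in one individual are treated
as a data-quality violation (error by default, keep-first optional).

**Odds-ratio models.** Logistic regressions (Newton/IRLS, tolerance 1e-8 on
the max coefficient change, 100 iterations max, Wald 95% CIs
`exp(b ± 1.96 se)`) estimate: (i) a six-level model — 2 carrier states × 3
score strata (low/intermediate/high = percentile ≤ 20 / 21–80 / ≥ 81), five
indicator contrasts against noncarrier-intermediate; (ii) OR per score SD
fit separately within carriers and noncarriers; (iii) a score × carrier
product term whose two-sided Wald p tests effect-size heterogeneity;
(iv) a percentile curve: predicted OR at percentile p and carrier state c is
`exp(b_carrier c + b_z (z_p − z_50))` relative to noncarriers at the median
percentile, other covariates cancelling at their means, with delta-method
CIs from the coefficient covariance. The curve model is additive (no
product term) by default — the stratified analyses it accompanies showed no
significant interaction, and the additive model gives the parallel
carrier/noncarrier curves on the log-OR scale; an interaction mode exists.
`z_p` is the empirical mean corrected score inside percentile bin p
(robust to non-normal corrected scores; a normal-quantile midpoint mode is
available), with empty bins linearly interpolated under a warning.

**Diagnostics.** Linearity is tested by a likelihood-ratio test of the
linear score model against one adding square and cube terms (df = 2).
Calibration is summarized in 20 fixed percentile bins (1–5 … 96–100) of
observed event fraction vs mean fitted probability.

**Penetrance.** A Cox model with age as the time-scale (time-to-event = age
at first diagnosis for cases, age at last follow-up otherwise; all subjects
at risk from birth) yields `F(t) = 1 − exp(−H0(t) exp(x'β))`, reported at
t = 75 years across percentiles × carrier states with remaining covariates
at their means. The partial likelihood is maximized by lifelines with
Efron tie handling (ages recorded in years tie heavily, and Efron is the
more accurate approximation there); the baseline cumulative hazard is
computed in-package with the Breslow estimator, which also provides the
variance increments for the CI. CIs use the complementary log-log
transform: `var(log H) ≈ Var(H0)/H0² + x' Cov(β) x`, neglecting the
baseline-coefficient covariance — a standard simplification that our
parameter-recovery tests show is adequate at the sample sizes used. No
delayed entry by default (all at risk from age 0, prevalent cases included
with time = age at diagnosis); left truncation at enrollment and an
incident-only restriction are available as sensitivity options.

**Retrospective power.** With the study size, case total, carrier count,
noncarrier OR/SD and carrier main-effect OR pinned to their observed
values, phenotypes are re-simulated conditional on the case total and the
carrier score effect is varied. Conditional phenotypes follow the
conditional-Bernoulli law — independent Bernoulli(p_i) given their sum —
with `p_i` from the logistic model and the intercept calibrated by 1-d root
finding so the expected case count equals the fixed total (the conditional
law is invariant to the intercept; calibration only matters for sampler
efficiency). Power at a carrier OR is the fraction of replicates in which
the two-sided Wald test on the product term rejects at alpha = 0.05;
replicates with separated or non-converged fits are counted and excluded
from the denominator. The detectable-OR bounds are found by bisection on
the log-OR scale on each side of the null, with replicates pooled at a
grid point until its comparison against the target power is resolved at
1.5 Monte-Carlo SEs (or a 4× replicate budget is spent) — without this,
one noisy midpoint evaluation can pin the bracket on the wrong side and
bias the bound outward.

Fixing the carrier main-effect OR matters: it concentrates carriers among
cases, moving their case probabilities off 1/2, which lowers the Fisher
information on the carrier score slope and widens the detectable bounds,
asymmetrically (information falls further at large slopes). Scores are
standard normal and redrawn each replicate by default; observed carrier
scores can be supplied instead (the real analysis would have fixed the
observed covariates — the difference is absorbed into the Monte-Carlo
tolerance).

## Conditional-Bernoulli samplers

Two exact samplers target the identical law. The dynamic-programming
sampler builds the Poisson-binomial recursion backward in log space
(an O(n·m) table) and draws sequentially; it also gives exact pmf values
and inclusion probabilities (forward–backward) and serves as the reference
at small n. The rejection sampler exploits invariance of the conditional
law under a common odds multiplier: odds are rescaled so the expected sum
equals the target, then independent Bernoulli vectors are drawn until the
sum hits the target exactly. Acceptance probability is
≈ 1/√(2π Σq(1−q)) (~0.7% at n ≈ 13,000), giving exact draws at a few
milliseconds each in vectorized batches — orders of magnitude faster than
a per-replicate DP table at biobank sizes. Probabilities of exactly 0 or 1
are forced before either sampler runs. `method="auto"` uses the DP sampler
when n·m ≤ 250,000 and rejection otherwise.

## Synthetic cohorts

The generator produces the statistical structure the estimators assume,
with known truth:

- **Ancestry structure.** Ancestral allele frequencies uniform on
  (0.05, 0.95); per-component frequencies by a Balding–Nichols draw
  `Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst)`; individual frequencies mix
  components through Dirichlet(1) admixture; dosages Binomial(2, p).
  Admixture proportions minus one redundant column are exported as the PC
  surrogates — they carry exactly the confounding the correction must
  remove, without an eigendecomposition. Default Fst 0.1 with 5 components
  (4 PC surrogates) produces continental-scale score shifts.
- **Carriers.** Bernoulli(0.005 by default); each carrier receives exactly
  one rare P/LP-class variant in one of the condition's genes (clinical
  screening cohorts observe no compound carriers).
- **Disease.** Cross-sectional status from a logistic model in carrier
  status (default OR 3), true standardized score (default OR 1.7/SD), age
  and sex, with the intercept solved by Brent's method so marginal
  prevalence hits its target (default 5%). Onset ages from a Weibull
  proportional-hazards model (shape 4, scale 130 years — baseline
  cumulative incidence ≈ 10% by 75, a common-disease scale) with
  independent uniform censoring at ages 55–80, emulating a middle-aged
  biobank's follow-up window.
- **Case-control sampling** subsamples uniformly within status strata, with
  no age matching: age enters the models as a covariate, so matching is not
  needed to validate the estimators.

What the generator does **not** emulate: linkage disequilibrium between
score variants, haplotypes, genotyping/imputation error, relatedness,
ascertainment other than case-control sampling, competing mortality, and
secular changes in diagnosis. Passing tests therefore demonstrate the
estimators' correctness under the assumed model, not robustness to these
real-data features.

## Numerical choices and degenerate inputs

- Missing dosages: mean imputation (2 × effect-allele frequency from
  non-missing individuals) by default; zero-imputation optional.
- Flanking-window exclusion: gene footprint = [start, end] from the region
  file, distance from footprint edges, bounds inclusive, so a variant at
  exactly `start − window` is removed. BED input is converted from 0-based
  half-open at the boundary; "chr" prefixes are stripped with a warning.
- Allele-frequency filter is a strict ">": a variant at exactly the
  threshold survives.
- Separation in logistic fits is flagged (diverging coefficients or
  singular information); per-gene carrier fits fall back to Firth's
  penalized likelihood and are labeled. Zero-carrier genes and empty
  six-level cells are reported as not estimable rather than raised.
- Degenerate generators behave explicitly: zero prevalence yields no cases
  (downstream fits then raise), censoring at age 0 yields no events, and a
  single-class outcome is rejected with a message.
- All randomness flows through numpy Generators seeded from the config;
  identical config + seed reproduces every output bit-for-bit.

## Problem sizes

Validation uses cohorts of 4,000–50,000 individuals with 40–200 score
variants, 100-replicate coverage checks, 1,000-replicate test-size checks,
and 500–600 replicates per power grid point — sizes at which every check
runs in seconds to a few minutes on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances. The power scenarios themselves
always run at the full observed study dimensions (12,852 and 19,264
individuals).

## Known limitations

- The percentile OR and penetrance curves condition on covariate means
  rather than averaging over the covariate distribution (a marginal rather
  than population-averaged contrast).
- The Cox CI neglects baseline–coefficient covariance (see above).
- Detectable-OR bounds inherit Monte-Carlo noise of roughly 2–6% of the
  bound at the default replicate budget.
- The power model omits adjustment covariates by default; the scenario
  toggle exists but the shipped scenarios fix only the observed study
  dimensions and effect sizes.
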