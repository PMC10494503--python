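# Methods

## Free 25(OH)D and the estimating equations

Circulating 25-hydroxyvitamin D is almost entirely carried by vitamin D
binding protein (VDBP, ~85–90%) and albumin, leaving a free fraction that
may better reflect biological vitamin D status than total 25(OH)D,
because VDBP concentration varies substantially between individuals and
across the six common Gc diplotypes (pairs of the Gc1f, Gc1s, Gc2 protein
variants).

The package ships two families of estimators:

1. **Regression equations** of the form

   free = b₀ + Σ bᵢ·tᵢ(xᵢ) + Σ c·ln(xⱼ)·ln(xₖ) + offset(diplotype)

   with tᵢ the identity for albumin and the natural logarithm for the
   skewed analytes (vitamin D metabolites, VDBP, iPTH, iFGF-23). The three
   shipped coefficient sets (full panel; full panel + diplotype offsets;
   clinical panel of albumin, 25(OH)D3, iPTH, 1,25(OH)2D3) are stored as
   JSON package data together with their published adjusted R² and
   development/validation RMSE pairs.

2. **The single-site binding-equilibrium (Bikle) calculation**
   free = total 25(OH)D / (1 + K_a1·[VDBP] + K_a2·[albumin]), with
   K_a1 = 8.00 × 10⁸ M⁻¹ and K_a2 = 6.00 × 10⁵ M⁻¹ and both carriers in
   mol/L. The free fraction 1/(1 + K_a1[VDBP] + K_a2[albumin]) lies in
   (0, 1] and the estimate is strictly decreasing in either carrier.

### Conventions and open choices

- **Logarithm base.** The sources do not state a base. We use natural
  logs: evaluating the clinical equation at the cohort's central predictor
  values gives ≈5.36 pg/mL with natural logs versus ≈4.75 with base-10,
  and only the former is consistent with the cohort's central measured
  value of ~5.3 pg/mL.
- **Molecular weights.** The equilibrium constants are per-molar, but the
  originating sources leave the molecular weights implicit. We adopt the
  values conventionally paired with them — 25(OH)D 400.64 g/mol, VDBP
  58 kDa, albumin 66.43 kDa — under which the equilibrium estimate at the
  cohort's median inputs (~5.31 pg/mL, denominator ≈ 3883) agrees with the
  median measured value. All five constants are overridable through
  `BindingConstants` / a JSON constants file.
- **Total 25(OH)D** in the equilibrium formula is the D3 + D2 sum (D2
  taken as 0 when absent).
- **Units are fixed**, not auto-detected: albumin g/dL, 25(OH)D3/25(OH)D2/
  24,25(OH)2D3 ng/mL, VDBP µg/mL, 1,25(OH)2D3/iPTH/free 25(OH)D pg/mL.
  CSV column names embed the unit. 1,25(OH)2D3 is pg/mL throughout.
- **Interaction terms** multiply the two log-transformed variables.
- **Negative predictions** are possible at extreme inputs; the evaluator
  returns the raw value (preserving validation statistics), the CLI flags
  non-positive estimates, and a clinical floor is available as an explicit
  `--floor` option (off by default).
- **25(OH)D2 below detection.** The assay floor is 0.2 ng/mL; the CSV
  reader substitutes a configurable floor (default 0.2) for missing or
  below-floor values before any log transform, with a logged warning. The
  generator applies the same floor at draw time.

## Validation metrics

Differences are **estimated − measured**, so overestimation yields a
positive bias. Limits of agreement are bias ± 1.96·SD with the sample
(n−1) standard deviation — exactly 1.96, no small-sample t correction, per
standard Bland-Altman practice. P15/P30 use the measured value as the
denominator, and a relative error of exactly 15%/30% counts as within.
Adjusted R² is 1 − (1 − R²)(n − 1)/(n − p − 1) with p the number of design
columns excluding the intercept. Subgroup reports with n < 2 are flagged
incomplete rather than fatal. Regression-based (proportional-bias) limits
of agreement and Deming/Passing-Bablok regression are out of scope.

## Equation development

- **Split.** Random development/validation partition; the development size
  is round(fraction·n) (banker's rounding; 370 → 247/123 at 2/3) with an
  explicit `dev_n` override to reproduce published sizes such as 244/126 —
  the original randomization cannot be recovered, only its sizes.
- **Forward selection.** Greedy best-improvement: starting from the
  forced-variable model, every remaining candidate is refitted each round
  and the best is added only if it improves the adjusted R² by at least
  the retention threshold (default 0.02). Ties break by candidate-list
  order; an optional pre-screen reorders candidates by univariable
  adjusted R² but never changes eligibility. Zero-variance candidates are
  skipped with a warning. The trace logs every evaluation (adjusted R²
  before/after, retained flag).
- **Blocks.** Gc diplotype enters as five indicators against Gc1f/Gc1f,
  season as three indicators against winter; sex, race, site, diabetes as
  single indicators. A block is added or dropped as a unit and counts its
  full column width in the adjusted-R² penalty.
- **Interactions.** After main-effect selection, all pairwise products of
  the retained *continuous* variables' transformed values are screened by
  the same threshold rule, greedily in decreasing-improvement order.
  Indicator blocks do not form interactions; a variable does not interact
  with itself.
- **Candidates.** The full pool is total 25(OH)D, 24,25(OH)2D3,
  1,25(OH)2D3, VDBP, Gc diplotype, age, sex, race, BMI, season, site,
  diabetes, eGFR, calcium, phosphate, iPTH, iFGF-23. Total 25(OH)D is the
  D2+D3 sum and is removed from the pool whenever D3 or D2 is forced, to
  avoid engineered collinearity. The "eq3" mode forces nothing and
  restricts candidates to the clinical panel (25(OH)D3, albumin, iPTH,
  1,25(OH)2D3, calcium, phosphate, eGFR, 25(OH)D2).
- OLS is fitted via statsmodels; rank-deficient designs raise an error
  naming the collinear columns. Coefficient inference is exposed
  (standard errors) but no hypothesis-testing workflow is built.

## Synthetic cohort generator

The generator emulates the marginal structure of a community-dwelling
70–79-year-old cohort of n = 370:

- **Log-normal biomarkers**, parameterized by median and log-scale with the
  scale derived from published quartiles as ln(Q3/Q1)/(2·z₀.₇₅):
  25(OH)D3 median 20.3 [13.4, 28.9] ng/mL; 25(OH)D2 0.33 [0.2, 1.2]
  (floored at 0.2); VDBP 253.3 [226.9, 284.1] µg/mL; 1,25(OH)2D3 40.2
  [30.2, 50.4] pg/mL; VMR 8.9 [6.5, 11.4]; iPTH median 34 pg/mL
  (midpoint of the middle-quartile medians; no overall median is
  published) with log-scale 0.45 chosen to match the published
  per-quartile spreads; iFGF-23 median 44 pg/mL, log-scale 0.40.
- **Truncated normals** for albumin (4.3 ± 0.4 g/dL), age (74.6 ± 2.9,
  clipped to 70–79.9), BMI (27.3 ± 4.6), eGFR (71.8 ± 19), calcium
  (8.9 ± 0.45), phosphate (3.6 ± 0.5).
- **Categorical mixes** from published counts: 53% female, 40% Black,
  51% Memphis, season mix 25/30/23/22% (winter/spring/summer/fall), 42%
  diabetes, Gc diplotype frequencies (0.195, 0.162, 0.246, 0.130, 0.211,
  0.057) for (Gc1f/Gc1f, Gc1f/Gc1s, Gc1s/Gc1s, Gc2/Gc1f, Gc2/Gc1s,
  Gc2/Gc2).
- **Dependence.** 24,25(OH)2D3 = VMR × 25(OH)D3 / 100 with an independent
  log-normal VMR draw, so the catabolite rises with its substrate
  (Spearman ≈ 0.75); iPTH couples to 25(OH)D3 through a Gaussian copula
  with latent correlation 2·sin(π·ρ/6) targeting a Spearman ρ of −0.3
  (configurable, 0 disables). All other predictors are independent.
- **Truth model.** Measured free 25(OH)D = truth equation (default:
  equation 2, the fullest specification; any `EquationSpec` can be
  substituted) + Gaussian noise with SD 1.16 pg/mL — the residual scale of
  the shipped equations — floored at 0.5 pg/mL to respect the observed
  lower range of measured values. With these defaults the grand mean of
  simulated measured free 25(OH)D across cohorts is ≈5.42 pg/mL,
  consistent with the published cohort mean of 5.37 ± 1.81 pg/mL.

**What passing tests do and do not show.** The generator reproduces
marginals and two coarse dependences, not the unknowable joint
distribution of a real cohort; covariates are independent of the
biomarkers, there is no assay-specific error structure beyond additive
Gaussian noise, and no longitudinal or quartile-conditional structure.
Recovery of coefficients and predictor sets on synthetic cohorts therefore
validates the estimation and selection machinery, not the clinical
accuracy of any equation in new populations.

### The selection-recovery scenario

Forward selection under a ΔadjR² ≥ 0.02 rule can only retain a predictor
whose term explains ≥ ~2% of response variance. Under the cohort-calibrated
defaults the clinical equation's albumin term (coefficient 0.275, albumin
SD 0.4 g/dL) explains ~0.3% and its iPTH term ~1.3% — so with realistic
spreads those variables are not recoverable by this rule, regardless of
implementation. Recovery tests therefore use
`cohort.recovery_scenario_config`, which widens the weak predictors
(albumin SD 1.6 g/dL, ln-iPTH SD 0.8, ln-1,25(OH)2D3 SD 0.5; sized by a
simulation power check so each true term's expected improvement clears the
threshold with margin at n = 1000) while keeping the stated noise SD of
1.25 pg/mL. This is an identifiability construction, not a claim about
realistic cohorts.

### Coefficient-recovery checking

Refitting the generating equation on a synthetic cohort (n = 5000, noise
SD 1.16) checks each of the 13 coefficients against its confidence
interval. Thirteen marginal 95% intervals jointly cover the truth only
~51% of the time even for an exactly unbiased estimator, so the test uses
Bonferroni-adjusted simultaneous 95% intervals (per-coefficient
|z| < z₀.₉₉₈), which keeps the family-wise false-alarm rate at 5% while
still failing for any genuinely biased coefficient at this sample size.

## Problem sizes and determinism

Test and acceptance computations use n = 370 cohorts (25 replicates for
calibration moments), n = 1000 for selection recovery, n = 5000 for
coefficient recovery and marginal checks, and n = 10 000 for categorical
frequencies and limit-of-agreement coverage — sizes at which the checked
quantities' sampling noise is several times smaller than the tolerance
asserted. Every stochastic path flows from a single `numpy` Generator
seeded from configuration; identical (config, seed) reproduce cohorts
bit-for-bit, and selection is deterministic given (cohort, config).

## Known limitations

- The shipped coefficients were derived in adults aged 70–79; applying
  them elsewhere is extrapolation.
- The Vermeulen-style free 25(OH)D equation and bioavailable
  (albumin-bound + free) 25(OH)D are not implemented.
- eGFR is consumed as a covariate; the cystatin C eGFR equation itself is
  out of scope, as is assay chemistry.
- The equilibrium model is single-site with diplotype-independent
  affinities; diplotype-specific binding constants are not modeled (the
  regression offsets of equation 2 absorb phenotype effects empirically).
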