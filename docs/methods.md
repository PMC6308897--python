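# Methods

## Model structure

All eight regression families are linear models of log10 live body mass
(mg) with log10 body length (mm) and optionally log10 maximum body width
(mm) as continuous predictors. Grouped families give every level of the
grouping factor — taxon, region, or the combined taxon × region factor —
its own intercept *and* its own slope for each continuous predictor (a full
interaction). Because not all taxa occur in both regions, taxon and region
cannot be crossed factorially; the combined factor carries one level per
*observed* combination (32 levels in the builtin database: 13 temperate,
19 tropical).

A model with separate intercepts and slopes per level is estimable as
independent per-level ordinary least squares regressions; the coefficient
estimates, pooled residual sum of squares, likelihood, and leave-one-out
errors are identical to the single full-interaction design matrix. The
implementation fits per level (via statsmodels OLS) and pools.

The families are described as generalized linear models in the source
literature, but the workflow — log10-transformed response, R², BIC, MSE
prediction error — is that of Gaussian identity-link regression, which is
exactly OLS; we implement OLS.

## Embedded parameters

Coefficients are stored as the published three-decimal values and never
re-derived (re-derivation would need the original specimen-level data,
which this package deliberately does not require). Significance stars are
carried as metadata only: non-significant coefficients (e.g. the negative
temperate Neuroptera length slope in the width family, an artifact of
long-thin morphology at low replication) are used verbatim in prediction
and flagged `nonsignificant_coefficient`.

Two metadata quirks in the published sampling table are resolved as
follows: temperate Pseudoscorpionida and Psocoptera print mass-range
fragments with no counts or length ranges; both are treated as absent from
the temperate region (their tropical rows are complete). Lookups for
unsampled combinations raise an error naming the nearest applicable
fallback family rather than guessing.

## Model-selection cascade

Prediction uses the fixed preference order
LWTR > LWT > LWR > LW > LTR > LT > LR > L — the order of the published
BIC/prediction-error ranking. Notably, width-bearing all-taxa models
outrank taxon-specific length-only models (LW above LTR): body shape beats
taxonomy at order-level resolution. When a more-preferred family is
inapplicable *only* because the record's taxon × region combination is
absent from the database (not because a measurement is missing), the
result carries `fallback_model`. The cascade is total: any record with a
positive length gets a prediction from family L at worst.

Extrapolation flags use closed intervals on the published per-combination
length ranges (a value equal to the printed minimum or maximum is in
range). The builtin metadata carries no width ranges, so
`extrapolated_width` can only fire for user-supplied metadata that
includes them.

### Back-transformation

Predictions are made on the log10 scale and back-transformed as `10^x`,
matching the source workflow, which applies no retransformation
correction. Because `E[10^X] > 10^{E[X]}` for noisy X, the naive
back-transform underestimates the conditional *mean* mass (it estimates
the conditional median); an optional Duan smearing mode multiplies the
back-transformed mass by the mean of `10^residual` from a fit
(`fitting.smearing_factor`). The default is the uncorrected transform so
that results are comparable with the published analysis.

## Model comparison

- **BIC** uses the full Gaussian log-likelihood including additive
  constants, with the parameter count equal to all regression coefficients
  plus one for the residual variance (the convention of mainstream
  statistical environments). Absolute BIC values are dataset-specific;
  only differences and weights are comparable across software.
- **BIC weights** are `exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2)` with `Δᵢ = BICᵢ − min BIC`,
  computed in shifted form so extreme spreads underflow to 0 rather than
  overflow. Weights are invariant to any constant shift of all BIC values.
- **R²** is `1 − RSS/TSS` on the log10 response, with one global TSS for
  all eight families so the values are comparable across the suite.
- **LOOCV MSE** is the mean squared leave-one-out prediction error of
  log10 mass. It is computed exactly via the PRESS identity
  `e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ)` per grouping level (leaving out an observation
  only perturbs its own level's fit); the test suite verifies equality
  with the literal refit-per-observation procedure to 1e−8 relative error.
- Ties in BIC all receive Δ = 0 and split the weight; suite results are
  sorted by BIC ascending, then model id.

A grouping level must contain at least (number of slopes + 2) observations
or fitting aborts with an error naming the level; the same applies if a
level's design is rank-deficient (e.g. exactly collinear length and width)
or a leave-one-out fold would be.

## Discrepancy analysis

The per-individual prediction discrepancy is the log response ratio
`Δ = log10(m_pred/m_obs)`: 0 means exact, positive means overestimation.
Its summary is the geometric-mean ratio `10^mean(Δ)`, reported also as
percent bias `100·(ratio − 1)` so that ratio 0.77 reads as −23%. The
size-dependence of the bias is an unweighted OLS fit of Δ on log10 length.

The disjunct analysis is defined for the two all-taxa families (LR, LWR):
each region's records are predicted with own-region (nondisjunct) and
other-region (disjunct) parameters. In the noise-free length-only case the
discrepancy is the analytic difference of the two regional lines,
`Δ(L) = (a_src − a_tgt) + (b_src − b_tgt)·log10 L`, which the tests
recover to 1e−10 (slope ±0.032 for the builtin LR truths); with noise the
temperate/tropical patterns are only approximately antisymmetric, so
symmetry is asserted only in the closed-form case. The published headline
ratios (0.77, 1.29, 0.92, 1.11) derive from the original 6,212-record
dataset; this package verifies the sign, magnitude class, and
length-dependence patterns on synthetic data instead (the simulated
length-only ratios come out near 0.76/1.30 at the default study geometry).

## Synthetic data

The generator emulates the structure the regressions assume, per
individual within a configured taxon × region group:

- `log10 L ~ Uniform(log10 L_min, log10 L_max)` — lengths log-uniform over
  the group's range (defaults: the published per-combination ranges). Only
  ranges are published, and log-uniform covers the regression domain
  evenly.
- `log10 W = α_w + β_w·log10 L + N(0, σ_w)` with defaults
  `α_w = log10(0.35)`, `β_w = 1`, `σ_w = 0.10`: isometric width at a
  typical arthropod width/length ratio of 0.35. No width–length
  relationship is published; these are package defaults, recorded in the
  output's truth sidecar and fully overridable.
- `log10 M = a + b_len·log10 L [+ b_wid·log10 W] + N(0, σ_m)` with the
  group's generating parameter set (defaults: the builtin taxon × region
  equations). The default `σ_m = √0.016 ≈ 0.126` makes the best family's
  refitted LOOCV MSE match its published prediction error.

All quantities are lognormal on the natural scale, hence strictly
positive. Output is deterministic given the seed. Larval records and
missing-width records can be injected per group to exercise the
preprocessing filters (larvae and, for the width suite, width-less records
are excluded before fitting).

One identifiability caveat: with `β_w = 1` and `σ_w = 0`, log10 width is
an exact affine function of log10 length and the two slopes of a
width-bearing family cannot be separated (the fitter raises a
rank-deficiency error). "Zero-noise" recovery therefore means `σ_m = 0`
with width scatter retained — every record still satisfies the generating
mass equation exactly.

What the simulations do *not* emulate: sampling-method biases, seasonal
size variation, taxon-specific shape distributions, heteroscedastic or
non-Gaussian residuals, and real covariance between length and width
beyond the isometric line. Passing recovery tests therefore demonstrate
the correctness of the estimation machinery, not the field accuracy of
the published equations.

## Problem sizes and numerical choices

The test suite uses zero-noise recoveries (asserted to 1e−9), 50 random
n=20 datasets for the LOOCV oracle equivalence (1e−8 relative), 100 seeds
at n=2,000 for stochastic slope recovery (±0.05, ≥95% of seeds), and one
n≈5,000 community for LOOCV calibration (0.016 ± 0.004) — sizes chosen so
the whole suite runs in seconds while keeping Monte-Carlo error well below
the asserted tolerances. Coefficient serialization fixes three decimals
(parameters) and two (metadata ranges), the published precisions, so
round-trips are exact. Units are fixed to mm and mg throughout; there is
no unit auto-detection.

## Limitations

- No prediction intervals or coefficient standard errors: the published
  tables carry significance stars but not covariances.
- No dry-mass conversion; the equations predict live (fresh) mass only.
- Subgroup regressions (hunting vs web-building spiders, beetle larvae,
  etc.) are out of scope; their parameters are not published in the main
  tables.
- Order-level taxonomy only, matched case-insensitively with no synonym
  resolution.
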