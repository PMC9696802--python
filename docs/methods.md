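# Methods

This note documents the statistical models behind `sccbb`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Poisson occupancy model (`plate_seeding`)

A homogenized cell suspension distributed across n wells deposits
X ~ Poisson(λ) cells per well, λ = (total cells)/(number of wells). The model
assumes the homogenization step is effective: no aggregation, clumping or
cell death between dilution and inoculation. All volumes cross the API in µL
and are converted to mL exactly once; densities are CFU/mL throughout.

* `density_for_blank_fraction`: a target blank fraction p₀ ∈ (0,1) inverts
  the zero class, λ = −ln p₀, density = λ/V. The canonical bench case —
  p₀ = 0.243 on a 384-well plate at 60 µL — gives 23.58 CFU/mL, i.e. 24 at
  the precision a dilution series can deliver. The inversion runs in this
  direction by design: the blank target is the controlled quantity, the
  density is derived.
* `calibrate_lambda`: λ̂ = −ln(n_blank/n_wells). The confidence interval is
  the exact Clopper–Pearson binomial interval on the blank proportion pushed
  through −ln (a decreasing map, so the proportion bounds swap roles).
  Exactness matters because a single plate gives at most a few hundred
  Bernoulli trials. n_blank = 0 raises: λ is then unbounded above and no
  point estimate is honest. Coverage of the 95 % interval is property-tested
  at ≥ 93 % over 1000 simulated 384-well plates (the exact interval is
  conservative, so empirical coverage sits above the nominal level).
* `dilution_acceptable`: the pilot-plate acceptance band on the blank
  fraction defaults to [0.24, 0.30], inclusive at both ends, and is
  configurable.
* `purity_given_growth`: P(all cells in an occupied well share a strain)
  = Σ_{k≥1} pmf(k) Σᵢ pᵢᵏ / (1 − pmf(0)). The Poisson series is truncated
  once the accumulated mass exceeds 1 − 10⁻¹², which bounds the truncation
  error explicitly; tests cross-check the sum against the closed form
  Σᵢ (e^{−λ(1−pᵢ)} − e^{−λ})/(1 − e^{−λ}) and against Monte-Carlo plates.
* `plan_dilution_series` decomposes stock/target greedily, largest step
  first (default cap 10×), matching bench practice of coarse-then-fine
  serial dilution; the step product equals the ratio to 10⁻⁹ relative.

## Screen bookkeeping (`plate_screening`)

Growth is called as blank-corrected OD600 ≥ threshold; the default
threshold 0.1 is a conventional turbidity floor, not a measured constant,
and should be tuned per reader and medium. Optical-distortion activity
calls are ingested as manual booleans (the assay is read by eye); a
distortion flag on a non-growth well is a validation error since the screen
only applies to turbid wells. Plate coordinates follow the A–P / 1–24
dialect with zero-padded columns (A01…P24).

Diversity: Shannon H in nats over genera with positive counts; Pielou
J = H/ln S, with J ≡ 0 for S = 1 (a one-genus collection has no evenness).
16S similarity bins are (99, 100], [98.65, 99], [0, 98.65): the species
threshold 98.65 % belongs to the intermediate bin, so "98.65–98.99 %" reads
as printed on collection reports; the three bins always partition the
collection.

## Plackett–Burman screening (`doe_screening`)

The 12-run design is the standard cyclic construction: eleven cyclic shifts
of the generator row (+ + − + + + − − − + −) plus an all-minus run; the
first k ≤ 11 columns carry the factors. Any balanced orthogonal 12-run PB
matrix yields identical effect/se/t statistics, so the generator choice is
statistically immaterial. Validation on run sheets checks balance and
pairwise orthogonality (which also catches duplicated or missing runs).

The fit is OLS of the intercept + k main effects; the reported effect is
the mean contrast (ȳ₊ − ȳ₋) = 2 × the coded slope. Residual degrees of
freedom come from that fit — 12 − (k+1), i.e. 6 for five factors — not from
dummy columns; with five factors this is the only error construction whose
t → p mapping reproduces a vendor-style screening table at two to three
printed decimals. Orthogonality forces a single shared standard error,
se = 2√(MSE/12); p-values are two-sided Student-t tails. An exactly
interpolating fit (zero residual SS, e.g. noiseless synthetic responses)
reports zero effects-scale uncertainty and p = 1 rather than 0/0 noise.

Steepest ascent is an arithmetic progression in natural units between a
start and end point (by default spanning the screened low→high range of
the carried factors); carry-over of a non-significant factor is an explicit
user choice, not an automatic α rule. `select_center` picks the
maximum-yield trial (earliest on ties — deterministic and conservative) and
warns when the maximum sits on the last trial, since the true optimum may
then lie beyond the explored path.

## Box–Behnken response surface (`doe_rsm`)

Only the 3-factor design is generated (12 edge midpoints plus optional
center replicates), the case the sequential workflow needs. Without center
points every run satisfies x₁² + x₂² + x₃² = 2, so the full quadratic model
matrix has rank 9 rather than 10 and exactly one quadratic term is
inestimable. `detect_aliasing` finds this by rank analysis; the default
sacrifice is the *last declared factor's* quadratic — a deterministic rule,
overridable by naming any quadratic term — and dropped terms are carried
through to the ANOVA with SS 0 and df 0. The intercept is never droppable.
Run the design with ≥ 1 center point when the quadratic in every factor
matters; the centerless design is supported because it is what a 12-run
budget forces.

The fit is OLS on coded variables. ANOVA uses partial (extra) sums of
squares against the full model — SS(term) = SSE(model without term) −
SSE(full) — so per-term SS need not add to the model SS; this matches the
convention of standard DOE software output. F = MS(term)/MS(residual),
p from the upper F tail. A fit whose residual SS is zero to within 10⁻¹⁰ of
the total SS is treated as interpolating and ANOVA raises.

Optimization over the coded cube is exact face enumeration: each of the 3ᵏ
faces fixes a subset of coordinates at ±1; the restricted quadratic's
stationary point solves a linear system in closed form and is kept when
feasible; vertices guarantee a candidate on every run. No iterative ascent,
no starting point, no convergence tolerance. A dense-grid oracle is kept in
the tests only. Reported natural optima are rounded to one decimal by
default (the resolution at which medium recipes are actually pipetted); raw
coordinates are always retained on the result object.

Coding between natural and coded units is the standard affine transform
(center, half-range step per factor). When the response surface follows a
steepest-ascent experiment, the intended coding is centers = best ascent
trial, steps = ascent increments; `FactorDef(low, high)` expresses this as
low = center − step, high = center + step.

## Activity statistics (`activity`)

`flag_active` is the two-sided pooled-variance (Student's) two-sample
t test with a direction gate: a sample is active only when p ≤ α **and**
its mean tension is below the control's. Equal-variance pooling rather than
Welch is deliberate — triplicate tensiometer reads from the same instrument
justify a common variance, and with n = 3 per group the pooled test is the
field's default. The gate makes the decision asymmetric under relabeling
even though the p-value is symmetric.

`estimate_cmc` fits tension = plateau + slope·min(log₁₀c − log₁₀CMC, 0),
the classic two-segment shape of a surfactant titration: linear decrease in
log concentration up to the CMC, flat above it. For a fixed breakpoint the
model is linear in (plateau, slope) and solved in closed form with slope
clamped ≤ 0 (the plateau may never sit above the descending leg); the
breakpoint is chosen by exhaustive least squares over 200 candidates spaced
between the 2nd and (n−1)th observed log concentrations — deterministic,
no initialization sensitivity, and the zero-noise recovery error is bounded
by the candidate spacing. A fitted slope shallower than −1 mN/m per decade
(configurable `min_slope`) means the curve is effectively flat and the
estimate reports "no CMC detected" (cmc = None) rather than a spurious
breakpoint. A consecutive rise > 1 mN/m on the descending leg triggers a
non-monotonicity warning. Estimates are equivariant under rescaling all
concentrations, as a concentration unit change requires.

## Synthetic data (`synthetic_data`)

* **Plates**: deposited counts ~ Poisson(λ); strain identities by
  sequential binomial splitting of each well's count across the abundance
  profile (exactly the multinomial law, vectorized across wells); per-cell
  growth survival ~ Bernoulli(growth_prob), so surviving counts are
  Poisson(λ·growth_prob) by the thinning property — purity checks against
  the analytic model should use this effective λ. OD is a two-level
  constant (blank baseline 0.04, occupied 0.54), sufficient for testing the
  growth caller; there are no growth kinetics, no cross-feeding, no
  interference between wells, and no strain-dependent culturability. Tests
  passing on these plates therefore validate the occupancy arithmetic, not
  the biology of any real community.
* **Run responses**: the true quadratic evaluated on the design plus iid
  Gaussian noise. Real fermentation replicates have heavier tails and
  run-order drift that this does not model.
* **Tension curves**: log-spaced concentrations spanning 1.5 decades either
  side of the breakpoint, the broken-stick mean plus iid Gaussian noise.
  Real curves bend smoothly through the CMC region; the sharp-kink
  generator is the estimator's own model, so recovery tests demonstrate
  correctness of the fitting machinery, not robustness to model
  misspecification.

Every generator takes an explicit integer seed, drives one private
`numpy.random.Generator`, and is bit-reproducible given (config, seed).

## Problem sizes and tolerances in the test suite

Monte-Carlo purity and blank-fraction checks run at 10⁶ wells (3 binomial
standard errors) in the end-to-end suite and 2×10⁵ wells in the unit suite;
the SS decomposition identity is asserted over 500 noisy simulated
experiments at 10⁻⁹ relative tolerance; CMC recovery uses 200 noisy
replicates (σ = 0.5 mN/m, median within 10 %); coefficient recovery at zero
noise is asserted to 10⁻¹⁰. Comparisons to printed statistical tables use
the tables' own precision: t and F statistics printed to two decimals are
checked through rounding-envelope bounds and p-values to ±5×10⁻⁴.

## Known limitations

* No most-probable-number (multi-dilution) λ estimation; one census, one λ.
* Only 2-level PB (12-run) and 3-factor BBD generators; no fractional
  factorials, central composites, or lack-of-fit tests (which need
  replicated center points).
* The box optimizer's face enumeration is exponential in the factor count;
  it is intended for the k ≤ 4 designs this workflow produces.
* The CMC model has exactly one breakpoint and a flat plateau; surfactant
  mixtures with two transitions need a different model.
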