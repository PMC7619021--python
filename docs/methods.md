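# Methods

This note documents the models implemented in `ringclim`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that had to be fixed for
reproducibility.

## Daily water balance

A single soil store of depth `root_depth` (mm) holds volumetric water
content θ between the wilting point θ_wp and the water-holding
capacity θ_hc; water above capacity drains the same day.  The daily
flux order is fixed (it must be, for bit-reproducibility): precipitation
is partitioned into snow (T̄ < 0 °C) or rain; snowmelt is released at
`snow_melt_factor`·max(T̄, 0) mm/day; throughfall is rain net of canopy
interception (only while in leaf) plus melt; potential transpiration is
`canopy_coef`·ET0 gated by phenology (a configurable dormant-season
coefficient, default 0, covers the off-season); actual transpiration is
reduced linearly below the relative-extractable-water breakpoint,
t_act/t_pot = min(1, REW/`rew_crit`); the store is then updated and
drainage removed.  Transpiration is additionally capped so θ cannot
undershoot θ_wp.  Daily mass balance — rain + melt − interception −
t_act − drainage = Δ(θ·root_depth) — closes to 10⁻⁹ mm and is
property-tested under random forcing.

ET0 is the FAO-56 Penman–Monteith reference evapotranspiration with
zero soil heat flux at the daily step and actual vapour pressure
rh·e_s(T̄min, T̄max).  One deliberate deviation: the net-longwave term is
floored at zero.  The FAO-56 cloudiness function 1.35·Rs/Rso − 0.35
extrapolates negative for heavily overcast days (Rs/Rso < 0.26), which
would turn a longwave *loss* into a gain and produce spurious
evaporative demand on dark, saturated, calm days; flooring restores
ET0 → 0 in that limit.

Topography enters through a slope/aspect factor: the ratio of daily
direct-beam irradiance on the tilted plane to the horizontal plane,
integrated over the day at 1-minute resolution from solar geometry,
applied to the direct fraction of global radiation only (constant
diffuse fraction 0.3).  Horizontal sites have factor 1 exactly.

Soil evaporation is not a separate flux: interception (default 15 % of
in-leaf rain) absorbs canopy losses, and transpiration is the only
flux that enters the growth factors, matching the climatic-water-
balance definition P − T_act.  Gross precipitation is used in that
definition (whether intercepted water should be excluded is ambiguous;
gross is documented here as the package's choice).

Defaults: θ_wp = 0.15, θ_hc = 0.35, root_depth = 800 mm,
rew_crit = 0.4, canopy_coef = 0.85, snow_melt_factor = 3 mm °C⁻¹ d⁻¹.
Under the default synthetic climate these give ≈ 400 mm annual
transpiration, ≈ 48 days/yr below REW 0.4 and ≈ 12 such days in
June–July — plausible values for a temperate beech stand on loamy
soil.  Calibration (`water_balance.calibrate`) fits any subset of soil
parameters to an observed θ series by bounded L-BFGS-B from a
seeded Latin-hypercube multistart with a Nelder-Mead polish; the
polish matters because the clipping kinks in the loss blunt
finite-difference gradients near the optimum.  Solutions pinned to a
bound are flagged.

## Phenology

Leaf unfolding (LU): daily forcing max(T̄ − T_base, 0)·(daylength/24)^e
accumulated from January 1; LU is the first day the sum reaches
F_crit.  The photoperiod term is a power of normalised daylength — the
minimal monotone choice; the exact functional form used by the source
models is not public.  Leaf coloring (LC):
LC = a − b_sp·T̄_spring + b_su·T̄_summer with b_sp, b_su ≥ 0, windows
May 1–Jun 30 and Aug 1–Sep 30, rounded and clamped to [LU+1, 365].

Defaults (T_base = 5 °C, e = 1, F_crit = 70, a = 270, b_sp = 1,
b_su = 2 d/°C) were chosen once so that the default synthetic climate
yields LU ≈ day 120 ± 2 and LC ≈ day 287, i.e. realistic
Central-European beech dates; they are substitutes for unpublished
calibrations, not reconstructions.  Because b_su > b_sp, uniform
warming lengthens the growing season (earlier LU, later LC) — the
qualitative behaviour expected under climate-change scenarios.

Fitting: LU by grid search over T_base and the exponent with an exact
inner solve for F_crit (predicted LU is a step function of F_crit, so
only the accumulated-forcing levels at observed event days can change
the prediction; the optimum is found on that finite candidate set).
LC by ordinary least squares with wrong-signed coefficients clipped to
zero.  F_crit is only weakly identified jointly with T_base and the
exponent; parameter-recovery tests therefore condition on the
structural grid.

## Growth factors

Seven summaries per (site, calendar year, season block): mean
temperature, Σt_act, ΣP − Σt_act, Σ(t_pot − t_act), mean θ, and the
counts of days with REW strictly below 0.4 and 0.7 (strict "<" by
default, configurable).  Season blocks: Jan–Mar, Apr–May, Jun–Jul,
Aug–Sep, Oct–Dec.  Lags act/−1/−2 are exact copies of earlier calendar
years (no recomputation), and (Oct–Dec, act) is illegal because ring
formation is assumed complete by the end of September — leaving 14
legal season–lag keys and 98 factor columns.

Standardisation pools sites and years within each (factor, season,
lag) stratum over a fixed historical reference window (default
1933–2022) and freezes the moments (μ, σ); scenario records are
transformed with the frozen moments so future change registers as
anomalies relative to the historical climate.  Pooling across sites
preserves between-site contrasts, which the model's site random
intercept absorbs.  Zero-variance strata (e.g. winter stress-day
counts that are identically zero) are flagged constant, set to 0 and
excluded from modelling.

## Age detrending

The curve w_age(a) = p_n/a + p_s + w_min − 10·k·softplus(0.1·(p_m − a)),
k = (w_min − w_50)/(p_m − 50), is evaluated with the overflow-safe
softplus max(x,0) + log1p(exp(−|x|)).  The juvenile term is read as a
quotient p_n/a: only the quotient yields a declining juvenile trend,
makes w_age(50) ≈ p_n/50 + p_s + w_50 and w_age(∞) = p_s + w_min, and
keeps magnitudes consistent with published per-species parameter sets
(which ship in `SPECIES_AGE_PARAMS`).

The fit targets the per-age mean width assembled across trees, not
individual rings, by nonlinear least squares with a deterministic
multistart over p_m ∈ {80, 120, 160, 220}.  w_min is an *input* (the
assumed minimum ring width): the curve depends on the five parameters
only through (p_n, p_s + w_min, k, p_m), so all five cannot be
identified jointly; fixing w_min resolves the ridge.  When not given
it defaults to the smallest per-age mean, which is only a good proxy
if the series reaches plateau ages.  r² is computed unweighted on the
per-age mean series.

## Sensitivity model and selection

The response is the tree-level residual series (site-mean screening is
used only for the correlation display); the only random effect is a
site intercept.  Preselection keeps, per legal season–lag key, the
water-category factor with maximal |Pearson r| against site-year mean
residuals plus mean temperature — at most 28 candidates — with ties
broken by a fixed factor order.

The random-intercept LMM is fitted by profiling the likelihood over
λ = σ_b²/σ_e²: given λ, GLS estimates and the profiled σ_e² are
closed-form in precomputed cross-products (X'X, X'y, per-group sums),
leaving a bounded one-dimensional optimisation (λ ∈ [10⁻¹⁰, 10⁶] on a
log grid, with the λ = 0 boundary checked explicitly).  Any column
subset reuses the same cross-products, so a full 28-candidate backward
elimination costs milliseconds; the selection-recovery simulations in
the test suite depend on this.  The fitter is cross-checked against
statsmodels MixedLM (ML log-likelihood to 10⁻⁵, REML estimates and
standard errors to ~10⁻⁴) on simulated data.

Model comparison uses ML likelihoods (AIC = −2ℓ + 2(p + 2), counting
fixed effects plus both variance components); the surviving model is
refitted by REML for reported estimates.  Elimination is greedy — one
term per iteration, the removal that lowers AIC most, ties broken by
candidate order, intercept never removed.  p-values are Wald t-tests
with containment degrees of freedom n − g − p.  Marginal and
conditional r² follow the variance decomposition
var(Xβ̂) / (var(Xβ̂) + σ_b² + σ_e²), adding σ_b² to the numerator for
the conditional version; single-site fits fall back to OLS and report
no conditional r².

A note on backward elimination by AIC: a null candidate survives
whenever its deviance contribution exceeds the 2-point penalty, which
happens with probability P(χ²₁ > 2) ≈ 0.157.  With ~25 null candidates
the *exact* recovery of a small true set is therefore essentially
impossible by design; the meaningful properties — verified by
simulation in the test suite — are that true predictors are retained
(containment) and that per-term false selection stays near that
nominal rate.

## Scenarios and projection

The baseline loop fills the projection calendar by pure index cycling:
projection day i receives source day i mod n.  (Calendar-aligned
replay would need a leap-day rule; index cycling preserves every
source value exactly and drifts the month-day alignment by at most a
couple of days over the century, which is immaterial for seasonal
aggregates.)  Scenario change is a seasonal additive temperature
offset (applied to tmin and tmax, with tmean recomputed) and a
multiplicative precipitation factor, both interpolated linearly from
no change at the projection start to end-of-century endpoints; the
five growth-factor season blocks double as the scenario season system.
Packaged endpoints for the high-emission scenario: +4 °C and ×1.20
precipitation in the winter blocks, +3 °C and ×1.05 in summer, with
shoulder seasons between; the moderate scenario uses half the change.
Humidity, wind and radiation are left unchanged (a pure delta-change
method).

Projection sets random intercepts to zero (population-level
prediction), averages the fixed-effect predictor over sites per year,
and summarises over consecutive 20-year blocks anchored at 2001 (so
2081–2100 is a block); partial blocks are excluded.  Lag factors for
the first projection years reach back into the historical record.

## Synthetic data

The weather generator produces: a sinusoidal mean temperature peaking
at day 200 with iid daily noise (sd 3 °C), a per-calendar-year anomaly
(sd 0.8 °C) giving seasonal means realistic interannual variance,
tmin/tmax = tmean ∓ 5 °C; per-season Bernoulli wet days with Gamma
amounts (shape 0.7, scale 8 mm → ≈ 880 mm/yr); Beta-distributed
sunshine fraction anti-correlated with wet days; Gaussian humidity and
Gamma wind.  It does *not* emulate: precipitation persistence (wet/dry
spells), temperature autocorrelation, spatial correlation between
sites, or the actual climate statistics of any real region.  Passing
tests therefore demonstrate correctness of the pipeline's arithmetic
and statistical machinery under known ground truth, not skill on real
meteorology.

Ring series are generated as the age curve plus a linear combination
of standardised factors (the generative inverse of the sensitivity
model), a site random intercept and iid residual noise; negative
widths are floored at 0.01 mm and flagged.  The default ground truth
plants +0.09 mm/SD on June–July soil moisture, −0.10 on June–July
temperature and +0.05 on previous-winter temperature, with site sd
0.15 mm and residual sd 0.25 mm — magnitudes chosen to be realistic
for temperate broadleaf sensitivity studies.  Soil-moisture
"observations" are a known parameterisation's trajectory plus clipped
Gaussian noise, so calibration has an exact oracle at zero noise.

## Problem sizes in the validation suite

The recovery experiment runs 63 sites × 92 years of daily simulation
once per session and 50 ring-noise replicates of the full
detrend–screen–select–fit chain (plus 30 pure-noise replicates), which
completes in a few minutes on one CPU thanks to the profiled LMM
fitter.  The reproduction script defaults to 16 sites and 10
replicates for a quicker end-to-end run; both scales exercise
identical code paths.

## Known limitations

- One soil layer, no groundwater, no lateral flow, no per-species
  stomatal control; a single (beech) phenology and soil
  parameterisation for all sites.
- The LC model is purely statistical; no chilling requirements.
- No temporal autocorrelation in model residuals (no prewhitening);
  no forward selection or exhaustive subset search.
- Scenario construction is delta-change only: no bias correction, no
  stochastic downscaling, no change in variability or in humidity,
  wind or radiation.
- Standard errors of stepwise-selected terms carry the usual
  post-selection optimism; they are reported as fitted, not corrected.
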