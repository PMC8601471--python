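# Methods

`yielduq` implements a statistical pipeline for projecting 30-year-mean
regional maize yield anomalies under climate change and decomposing the
projection uncertainty into its parameter and climate-forcing components.
This note documents the model, the numerical choices, and what the
synthetic study does and does not demonstrate.

## The yield model

County-year yields (bushel/acre) are modelled as

    yield_it = f(x_it; β) + u_t + v_i + ε_it

where `x_it` are six growing-season weather covariates — growing degree
days (GDD, 10–29 °C clamp), extreme degree days (EDD, above 29 °C), mean
daily maximum and minimum temperature, total precipitation, and mean
vapor pressure deficit (VPD) — and `f` is a polynomial with, per
variable, no term, a linear term, or linear+quadratic terms, plus an
intercept: 3⁶ = 729 candidate *structures*, 13 coefficients in the full
model. Year effects `u_t` absorb technology, price and CO₂ trends;
county effects `v_i` absorb time-constant site quality.

The growing season of a county-year is the 183-day window starting the
first day the *trailing* 21-day moving average of daily mean temperature
reaches 10 °C. Trailing (rather than centered) alignment is causally
computable in real time and reproducible at year boundaries; 183 days
fixes "six months" deterministically across calendars. Degree-day terms
are season sums; precipitation is a season total; temperatures and VPD
are season means (degree-day regressors are already sums; mean
temperature with total precipitation is the convention of the underlying
crop-regression literature).

VPD uses the Magnus-type saturation pressure
`e_s(T) = 6.112·exp(17.269·T/(T+237.3))` hPa at the daily mean
temperature, scaled by `1 − RHmean` with RH as a fraction. The
`+237.3` sign is the physically correct form; an `as_printed` escape
hatch flips it for strict reproduction of a published misprint.

### Estimation

Year and county effects are estimated **jointly** with the weather terms
in one least-squares fit (dummy coding, first year and county folded
into the intercept) — the standard panel approach, avoiding
omitted-trend bias. The default fit is **unweighted** OLS; area weights
enter only when county values are aggregated to the region. This is a
deliberate choice: if the fit used the same area weights as the
aggregation, the estimated year effects would absorb exactly the
area-weighted regional residual, the observed regional anomalies would
coincide with the model hindcast up to estimation error, and the
plausibility band below would degenerate. An area-weighted fit remains
available behind a flag.

Structure selection minimizes 10-fold cross-validated RMSE; folds are
random over county-year observations with a stored seed (by-year folding
is a flag). The CV loop residualizes the response and the twelve weather
columns against the fixed-effect space once per fold (QR projection), so
each of the 729 candidate fits is a ≤12-column least-squares problem and
the exhaustive search takes about a second on a 1,200-row panel. RMSEs
within 1e-8 bu/acre are treated as ties, broken by fewer terms and then
lexicographic level order, so a noiseless panel selects the minimal
adequate structure deterministically.

A caution established quantitatively during development: k-fold CV model
selection is *inconsistent* — each boundary inclusion decision (a true
but weak term, or a spurious term) flips with a probability that does
not vanish as the noise shrinks, because the t-statistic of a null term
is noise-scale-free. On a 30-county × 40-year panel the probability of
recovering the generating structure *exactly* plateaus around 20–25%
regardless of residual SD. Selected structures are almost always within
one inclusion level of the truth; exact recovery should not be expected
at this panel size.

### Anomalies

Per-observation anomaly = yield − estimated year effect (intercept
included, so the year level is fully removed). Regional annual anomaly =
area-weighted county mean. A single area-weighted historical mean is
then subtracted so the weighted mean of the historical regional series
is exactly zero (tolerance 1e-9, asserted). County effects are *not*
removed — the analysis works in regional anomaly space.

## Pre-calibration

Parameter uncertainty is sampled by plausibility screening rather than a
likelihood. The screen has three parts:

1. **Sampling box.** Independent uniform ranges per full-model
   coefficient: best estimate ± 10·SE, widened to ± 50·SE for the EDD
   terms (whose full-model and selected-model estimates differ most).
   `build_ranges` reproduces the published range table from the
   published estimates; a strict-table mode reproduces the printed
   bounds verbatim, including one row whose printed bounds are
   inconsistent with the ±10·SE rule (an exponent misprint).
2. **Plausible band.** The symmetric envelope around the full-model
   regional hindcast whose half-width is the ⌈0.95·n⌉-th smallest
   absolute residual |observed − hindcast| over the historical years —
   the exact minimizer of the width subject to 95% coverage; no
   optimization loop.
3. **Acceptance.** A candidate is accepted when its regional hindcast is
   inside the band for **all** historical years (the stricter of the two
   readings of "falls within the plausible range"; a `coverage_accept`
   flag implements the lenient fraction-of-years variant). Because the
   regional hindcast is linear in the coefficients (`h = R β − c`, with
   `R` the year × 13 matrix of area-weighted regional regressor means),
   screening a chunk of candidates is one matrix product.

Proposals come from a chunked Latin hypercube stream: an independent
random stratum permutation per dimension, uniform jitter within strata
generated in fixed-size blocks keyed by absolute sample index, so the
stream is deterministic under a fixed seed and exactly invariant to the
consumer's chunk size. Bookkeeping holds one int32 permutation per
dimension (O(n) memory; practical up to a few 10⁷ points); candidate
evaluation is chunk-bounded.

### Desk-scale feasibility and the Gaussian-proposal screen

Blind Latin hypercube sampling over the ±10/50·SE box is how the
published analysis was run — at 10¹⁰ proposals for ~2·10⁴ acceptances
(≈10⁻⁶). At this package's study scale the geometry is harsher: with
1,200 observations the coefficient SEs are ~5× larger, so the box is
~5× wider per dimension in hindcast units while the band half-width is
similar. Measured on the default study (2·10⁷ LHS proposals): no
proposal came within a factor 4 of the band; the extrapolated acceptance
rate is ~10⁻¹¹. No desk-feasible proposal count produces a usable
ensemble this way, and `run_precalibration` reports that honestly.

`run_precalibration_gaussian` therefore applies the *identical*
acceptance test to proposals drawn from the regression's sampling
distribution N(best, 3²·Cov), truncated to the sampling box. The
inflation factor 3 keeps the proposal much wider than the acceptance
region (acceptance ≈ 5–15%), so the screen still discovers acceptable
parameters far from the best estimate; accepted samples satisfy exactly
the same band and box constraints as LHS acceptances would. The
covariance is factored through the correlation matrix because the
coefficient scales span ~10 orders of magnitude.

## Climate forcings

Ensemble members are daily projections treated as equally likely. The
delta climate shifts an observed 30-year record (1981–2010 where the
record covers it) by per-county differences (temperatures) or ratios
(precipitation, relative humidity) between the ensemble-mean
projection-window mean and the hindcast-window mean. Per-county (rather
than regional) deltas preserve spatial climatology gradients. RH is
clamped to [0, 100] after scaling and the tmax ≥ tmin ordering is
restored where unequal temperature deltas would flip it. Two delta
properties are asserted as invariants: an additively warmed climate
never lowers seasonal EDD, and the delta climate's temperature variance
equals the observational variance to 1e-9 — the method's documented
blind spot (it freezes variability, underestimating future extremes).

In the synthetic study the generated historical record serves as both
the delta baseline and the hindcast side of the delta means (there is no
downscaling bias to emulate).

## Projections and uncertainty decomposition

For a forcing and a window, each year's county covariates go through the
polynomial to an area-weighted regional anomaly; the 30-year mean, minus
the historical mean of the reference hindcast (the *center*), is the
projection. The center puts projections in the same normalized anomaly
space as the observations: reference parameters on a stationary climate
project ~0.

Three stages: parameters-only (accepted ensemble × the fixed delta
reference), forcing-only (best estimates × the 18 members), and both
(full Cartesian grid). The delta climate is excluded from the varied
forcings by default (it is the fixed reference the ensemble is
contrasted against); a flag includes it for the 19-forcing count.
The cumulative decomposition computes, per stage, conditional SDs with
the other factor fixed, averages them into a marginal SD, and expresses
each as a percentage of the both-stage SD — **SD ratios, not variance
ratios**, so single-source percentages need not sum to 100 and the
incremental attribution depends on the order sources are added; both
orderings are reported rather than hidden. All SDs are population
(ddof=0) statistics, which makes the law-of-total-variance identity on
the Cartesian grid exact (asserted to 1e-9). Quantiles use linear
interpolation of order statistics; skewness is adjusted Fisher–Pearson.

## The synthetic study

The generator emulates the shape of the real inputs: 30 counties ×
40 years of daily weather (tiny: 5 × 15; both with 18 or 3 projection
members), and yields from a known coefficient vector.

Weather: sinusoidal seasonal cycle (base 12 °C, amplitude 14 °C, peak
mid-July) with county offsets (SD 1.5 °C), regional (0.8 °C) and
county-year (0.4 °C) interannual anomalies, white daily noise (3.5 °C),
and a historical warming trend of 0.25 °C/decade. The diurnal range
(mean 13 °C) varies by county (SD 1.5) and county-year (SD 0.8) — without
that, season-mean tmax and tmin are exactly collinear. Precipitation is
intermittent-exponential (wet-day probability 0.35, mean 6 mm) with a
lognormal county-year wetness multiplier (log-SD 0.3); relative humidity
has county climatologies and county-year anomalies (SD 4%). These
settings land the covariates at corn-belt-like magnitudes under the
clamped definitions: GDD ≈ 1950 ± 250, EDD ≈ 160 ± 90, season
precipitation ≈ 430 ± 160 mm, VPD ≈ 8 ± 1.5 hPa.

Members share the historical climatology and differ in future trend
(mean 0.55 °C/decade — a high-forcing scenario — with a right-skewed
spread of scale 0.15, mirroring the right-skewed climate-sensitivity
distribution of multi-model ensembles) and in variance inflation
(uniform 1.0–1.35).

Yields: truth polynomial + base level 150 bu/acre (folded into the
effective intercept) + a 1.8 bu/acre/yr technology trend (zero in the
first year) + county effects (SD 8, zero for the first county) + residual
noise of total SD 15 bu/acre, of which 75% is carried by three shared
spatial factors (year shocks with county loadings) and the rest is
independent. Spatially correlated residuals are a first-order feature of
real county yields (drought and pest patterns span counties) and are
what keeps the observed regional band (~4–6 bu/acre) wide relative to
estimation error; with purely independent noise the band collapses and
the screening stage becomes vacuous. County areas are log-uniform on
2·10⁴–5·10⁵ acres — skewed weights, as in reality.

The `default` preset uses the selected-model coefficients as truth; the
`realistic` preset uses the published full-model coefficients; `cold` is
a preset whose 21-day moving average never reaches 10 °C, exercising the
no-growing-season path.

### What the synthetic tests do not show

- The generator draws from the same polynomial family the pipeline fits;
  real structural error (missing interactions, slope heterogeneity) is
  represented only by the spatial residual factors.
- Daily noise is white; the pipeline consumes seasonal aggregates, so
  autocorrelation would matter little, but sub-seasonal extremes are
  underdispersed relative to real weather.
- At far-future warming the published polynomial's convex Tmin² and EDD²
  terms flip the response positive (warm members can project gains), so
  the far-window joint distribution is right-skewed in this world; the
  lower-tail-expansion headline is demonstrated on the near window and,
  as a controlled property, on a constructed concave heat-response model.
- Exact structure recovery is capped by CV-selection inconsistency (see
  above); the corresponding end-to-end check is expected to fail at its
  literal ≥80% threshold and is retained unweakened.

## Problem sizes

The shipped study sizes are: 30 counties × 40 years (1,200 county-years)
with 18 members per window; 10⁶ screening proposals (≈5·10⁴–10⁵ accepted
under the Gaussian screen, comfortably past the ~5·10³ where the
convergence diagnostic's running mean and SD flatten); up to 5,000
accepted samples × 18 members in each staged grid. The full acceptance
run completes in a few minutes on one core.
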