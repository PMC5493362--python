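# Methods

## Model

`fuzzyair` implements a Mamdani fuzzy inference system mapping four daily
exposures to a predicted daily count of hospitalizations for asthma and
pneumonia.

**Inputs and output.** Each input variable carries two trapezoidal
membership functions, *good* and *bad*; the output carries five
(*very low*, *low*, *medium*, *high*, *very high* — MBX/BX/MED/ALTO/MALTO
in the Portuguese acronyms of the source field). A trapezoid (a, b, c, d)
is 0 at/below a, rises linearly to 1 at b, is 1 on [b, c] and falls to 0 at
d; a = b or c = d denotes an open shoulder held at full membership beyond
the flat edge, and b = c a triangle.

**Inference.** Rule firing is the minimum of antecedent memberships
(conjunctive AND), implication is truncation of the consequent at the
firing strength, aggregation across rules is the pointwise maximum, and
defuzzification is the area center (centroid) of the aggregated set on an
evenly discretized output universe. No product/sum variants, rule weights,
hedges or alternative defuzzifiers are offered.

**Rule base.** The 16 rules enumerate {good, bad}⁴. Only the two extreme
rules are fixed by the application (all good → very low; all bad → very
high); the middle 14 follow a monotone severity map from the number of bad
antecedents (0 → very low, 1 → low, 2 → medium, 3 → high, 4 → very high).
The map — and, alternatively, an explicit rule list through the engine
API — is configurable, since intermediate rules in this kind of model are
expert judgements, not measurements.

## Default parameters

Membership breakpoints are design choices, not published values; they are
anchored to the regulatory reference points for each pollutant and to the
observed variable ranges, and every one of them can be overridden in a
YAML/JSON `ModelConfig`.

| variable | universe | good | bad | anchor |
|---|---|---|---|---|
| PM10 (µg/m³) | [0, 120] | (0,0,25,50) | (25,50,120,120) | moderate-air band starts near 50 |
| O3 (µg/m³) | [0, 200] | (0,0,80,160) | (80,160,200,200) | 160 µg/m³ air-quality standard |
| SO2 (µg/m³) | [0, 30] | (0,0,10,20) | (10,20,30,30) | WHO 24-h guideline 20 µg/m³ |
| TEMPap (°C) | [0, 30] | (12,18,30,30) | (0,0,12,18) | cold = harmful direction |
| admissions | [0, 16] | five terms: (0,0,2,4), (2,4,4,6), (5,8,8,11), (10,12,12,14), (12,14,16,16) | | observed 0–16 range |

Cold apparent temperature is treated as "bad" (winter excess of respiratory
admissions); if a thermal-comfort reading (mid-range good) is preferred,
the TEMPap trapezoids can be swapped in config. The output discretization
defaults to 1001 points; at that resolution the centroid differs from a
200 001-point quadrature oracle by < 0.01 admissions, well under the 0.05
the tests enforce.

**Apparent temperature.** When a series provides ambient temperature and
relative humidity instead of TEMPap, the package computes a Steadman-type
index: dew point T_d from the Magnus approximation (constants 17.27,
237.7 °C), then AT = −2.653 + 0.994·T_a + 0.0153·T_d². The formula is
isolated in one function (`apparent_temperature`) so an alternative index
can be substituted. Two caveats: RH must be in (0, 100] (the dew point is
undefined at RH = 0), and the quadratic T_d² term makes the index
non-monotone in humidity where T_d < 0 °C (cold, dry air); monotonicity
holds over the physiological range the model targets.

## Validation procedure

Predictions from day-*t* exposures are scored against observed admissions
on day *t + lag* for lags 0–2 (exposure leads outcome). Per lag:

* **Pearson r** with a two-sided p-value (t distribution, n − 2 df);
  undefined (raised as an error) for fewer than 3 pairs or zero variance.
* **ROC AUC** of predictions against dichotomized counts, positive =
  admissions > threshold (default 2). The AUC is the Mann–Whitney
  estimator (ties ½); its 95% CI uses the Hanley–McNeil standard error
  with Q1 = A/(2−A), Q2 = 2A²/(1+A) and the 1.96 normal quantile, clamped
  to [0, 1]. Hanley–McNeil was chosen over DeLong for its closed form and
  symmetric intervals; DeLong could be added without API change.

Missing pairs are dropped and counted; no multiple-testing correction is
applied across lags. The default threshold of 2 reads "up to 2 daily
admissions" as the negative class; because that phrasing is ambiguous the
threshold is a first-class parameter (`--threshold`).

## Synthetic data generator

The generator stands in for monitoring-station exposures and health-system
admission counts, which are not publicly deposited. Per exposure it draws
a stationary Gaussian AR(1) path, rescales to a target mean/SD and
truncates to target bounds. Defaults reproduce the published 2007 summary
statistics: PM10 26.0 ± 11.3 (8–89), O3 91.0 ± 67.9 (17–162), SO2
3.8 ± 3.3 (0.9–27) µg/m³, TEMPap mean 17.9 °C over 5.7–20.2. The printed
TEMPap SD (0.9 °C) is inconsistent with its own printed range, so the
generator honors mean/min/max and floats the SD to a plausible 2.5 °C.

Admissions on day *t* are Poisson with log rate
β₀ + Σ_p Σ_lag β_{p,lag}·z_{p,t−lag}, where z is the exposure standardized
by the generator's own mean/SD (so each β reads as log-rate change per SD),
β₀ = log 4.9 matches the observed mean of 4.9 admissions/day, and counts
are capped at 16 to mirror the observed maximum (a fixture convention, not
an epidemiological claim). Days before the first available lagged exposure
take a neutral zero contribution.

**Persistence default.** The AR(1) coefficient defaults to ρ = 0.2. The
generator's contract is that a single planted lag is identifiable by the
validation pipeline (the planted-lag recovery property below), and
stronger persistence smears an association across neighbouring lags: at
ρ = 0.5 the lag-1 effect is recovered as the AUC-maximum lag in only
~80–85% of replicates, versus ~93% at ρ = 0.2. That smearing is real —
strongly autocorrelated exposure series genuinely cannot pin an effect to
a single lag — so ρ is exposed for users who want to study it; the default
keeps the planted lag recoverable.

**What the generator does not emulate:** seasonality, day-of-week effects,
overdispersion, skewed exposure distributions (truncated Gaussian, not
lognormal — published summaries don't constrain the tail), and
measurement error. Passing tests therefore demonstrate that the pipeline
recovers structure the generator plants under clean conditions; they do
not certify performance on real admission series.

## Numerical choices and degenerate inputs

* Inputs outside a variable's universe are clamped to [lo, hi] before
  fuzzification (real readings can exceed historical ranges).
* Input variables must cover their universe (some term nonzero
  everywhere); with the complete rule base this guarantees at least one
  rule fires for any input. If aggregation is nonetheless identically zero
  (possible only with hand-built, non-covering configurations) the package
  raises a degenerate-aggregation error rather than returning a default.
* Output-variable coverage is *not* required: partial/disjoint consequents
  are legitimate in experimentation, and the degenerate-aggregation error
  covers the pathological case.
* The centroid is unique whenever any degree is positive; no tie-breaking
  is needed. Doubling the resolution moves predictions by < 0.02
  admissions (tested).
* Replicated experiments derive child seeds via `numpy` `SeedSequence`;
  identical seeds give byte-identical series and reports end-to-end.

## Experiment sizes

The shipped experiments use a year of daily data (n = 365, matching the
study design the model targets), 50 replicates for the planted-lag
recovery and null-calibration experiments, 10⁴ random inputs for the
boundedness check, and 100 random activations against a 200 001-point
quadrature oracle for centroid accuracy. The planted-lag recovery rate at
the defaults is ≈ 93% (estimated over 300 replicates), so a 50-replicate
batch at the ≥ 45/50 bar retains some sampling noise; the null mean AUC
sits at 0.50 as required.

## Known limitations

* Membership breakpoints approximate drawn (not printed) curves; they are
  declared design decisions, and conclusions sensitive to them should be
  re-run over a breakpoint sweep via `ModelConfig`.
* The model treats city-wide pollutant concentrations as homogeneous
  exposures — a single monitoring station stands for the whole population.
* Predictions compress extremes (centroid effect): observed 0-admission
  and 16-admission days map to ≈ 1.6 and ≈ 14.4 at best.
* The validation is correlational; AUCs against dichotomized counts do not
  establish causality, and lag-specific attribution degrades as exposure
  persistence grows (see the ρ discussion above).
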