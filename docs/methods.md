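# Methods

## The attribution model

`vegtherm` treats the morning rise of land surface temperature as the
observable that best isolates how vegetation modulates the surface energy
balance. Between roughly 07:00 and 11:00 local solar time LST rises nearly
linearly; the daily median of finite-difference rates over that window,
d(LST)/dt (K/h), integrates the diurnal cycle while staying robust to cloud
gaps and to the timing of the afternoon peak. Where vegetation dissipates
energy efficiently the surface warms slowly; where dissipation is weak, or
where greening darkens the surface, it warms fast.

Because vegetation, moisture and radiation co-vary in space, the net FVC
effect is identified by **spatial conditioning**: pixels are tiled into
bins of near-identical long-term mean soil moisture (±0.0025 m³/m³) and
downwelling shortwave (±1.25 W/m²), and within each bin an OLS fit of the
annual-mean rate on annual-mean FVC gives β_FVC. The space-for-time
reading — that across-pixel differences within a bin stand in for temporal
change at one location — is an interpretive label, not a computation; no
causal adjustment is performed beyond the stated conditioning. Two-sided
t-tests at α = 0.05 classify bins as cooling/neutral/warming with **no
multiple-testing correction across bins**; this mirrors per-bin
significance usage and is a known limitation.

Mechanism diagnostics: the dissipation efficiency β_Eff is the negated
slope of d(LST)/dt on concurrent LST, multiplied by the force-restore
normalization 32.5 to be unitless (`DISSIPATION_NORMALIZATION`, a named
constant, never inlined); albedo sensitivity repeats the within-bin fit
with mean albedo as the response. The tropical assessment regresses annual
LST on NDVI, precipitation and radiation per pixel, converts β_NDVI to
ΔLST per 1% **relative** NDVI increase (β_NDVI × 0.01 × mean NDVI — not an
absolute 0.01 step), and summarizes the dryland dilution of domain-wide
cooling as reduction = 100·(mean ΔLST|humid − mean ΔLST|all)/(mean
ΔLST|humid), with the median analogue. For a two-valued map this reduces
algebraically to 100·f·(1−r), f the dryland fraction and r the
dryland/humid ΔLST ratio, which the tests assert.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| θ half-width | 0.0025 | m³/m³ | conditioning tolerance |
| R_S half-width | 1.25 | W/m² | conditioning tolerance |
| dryland threshold | 500 (±200 sensitivity) | mm/yr | strict `<`; boundary pixels are humid |
| α | 0.05 | — | two-sided significance |
| morning window | [07:00, 11:00) | local solar | half-open: unambiguous adjacency at boundaries |
| DTR times | 13:30 − 06:00 | local solar | assumed daily max/min |
| afternoon window | [12:30, 14:30] | local solar | mean daily peak temperature |
| max QC gap | 2 | h | caps slope attenuation from long spans (see below) |
| min valid days | 30 | days/yr | annual rate means; configurable |
| min pixels/regressor | 10 | pixels | 20 for the 2-parameter fit, 40 for the seasonal 4-parameter fit |
| bootstrap reps | 1000 | — | percentile CIs |

Gap handling: increments may span QC-flagged samples, covering a longer
interval, up to 2 h; longer gaps yield no increment. An uncapped span would
let a single increment straddle most of the window and attenuate the
median. Neither the gap cap nor the 30-valid-day floor is externally
prescribed; both are configurable package choices.

The dissipation regressor is the **midpoint LST** of each increment rather
than the left endpoint. For an exponential relaxation with rate k sampled
at spacing Δ the fitted slope is then exactly −(2/Δ)·tanh(kΔ/2): a relative
bias of order (kΔ)²/12 (&lt;0.01% for kΔ = 0.025) instead of the O(kΔ/2)
first-order bias of an endpoint regressor. Increments for β_Eff come from
the full diurnal cycle by default (window configurable).

The Welch (unequal-variance) t-test backs both the dryland reduction
significance and the group contrasts; the reduction's default comparison is
"all pixels vs humid-only" (the with/without-drylands form), with a
disjoint "dryland vs humid" variant available — the variant is what the
calibration tests exercise, because only disjoint samples give the nominal
5% level (the overlapping form is conservative by construction).

## The synthetic generator

The generator emulates the *statistical* structure the analysis assumes —
it is not a land-surface model:

- **Aridity gradient.** Scene columns span annual precipitation from 100
  to 1500 mm/yr. Soil moisture and radiation take one discrete level per
  column, stepping by exactly one conditioning-bin width (0.005 m³/m³,
  2.5 W/m²), so each column is one bin. A monotone staircase rather than a
  smooth ramp: it keeps corr(precip, θ) = 1 while making the within-bin
  baseline exactly constant, so the planted β_FVC is recoverable to
  machine precision in noise-free mode.
- **Diurnal cycle.** Piecewise linear — flat to 06:00, ramp of slope
  r = r₀(θ, R_S) + β_FVC·FVC (+ per-day noise) to 12:00, plateau to 14:30,
  linear decay to 24:00 — rather than sinusoidal, so the morning median
  rate equals the ramp slope exactly and DTR = 6 h × slope. r₀ is affine
  with fixed coefficients (6.0, −6.0 per m³/m³, +0.005 per W/m²), so bins
  share baselines. `noise_sd_lst` (default 0.5 K) is the sd of the
  accumulated morning-window error; per-day slope noise is that divided by
  the 4-h window.
- **FVC** is monotone in precipitation plus a deterministic ±0.2
  within-column spread (regressor variance survives noise-free mode) plus
  N(0, 0.02) noise, clipped — not resampled — at [0, 1]; clipping gives a
  reproducible, documented bias at the extremes.
- **Albedo** declines with FVC at −0.25 per unit FVC in drylands and
  −0.125 in humid columns (planted 2× contrast), noise sd 0.01.
- **Annual panels** (19 years) plant β_NDVI = −10 K/NDVI in drylands and
  −12.5 in humid pixels — with the generator's NDVI climatology this makes
  mean ΔLST per 1% greening about −0.03 to −0.05 K (dry) versus −0.08 to
  −0.1 K (humid) — plus β_P = −0.002 K/(mm/yr), β_RS = +0.02 K/(W/m²),
  interannual noise 0.3 K, and an optional linear LST trend.
- **Cloud gaps** drop each 15-min sample independently with probability
  0.2. Noise is Gaussian, independent across pixels and days — the
  simplest structure consistent with the regression error term.
- **Determinism:** one `numpy.random.default_rng(seed)` drives everything;
  identical configs give bit-identical scenes.

What the generator does **not** emulate: radiative-transfer physics,
spatially correlated cloud fields, orbital sampling, NDVI saturation in
dense forest, retrieval error structure. Passing recovery tests therefore
show the *estimators* are correct and calibrated under the stated
assumptions; they do not validate the space-for-time assumption itself on
real scenes, nor robustness to structured (autocorrelated) noise.

## Numerical and design choices

- Bins **tile** the (θ, R_S) plane anchored at 0 with widths twice the
  half-widths; stated "±" tolerances could also be read as sliding
  windows, but tiling gives deterministic, non-overlapping membership and
  every member provably lies within tolerance of its bin center.
- Precipitation exactly at the dryland threshold → humid (strict `<`).
- Seasonal-split tie days (FVC equal to the pixel median) → high-FVC half,
  for a deterministic partition.
- Area fractions are pixel-counted by default; optional weights supported.
- Degenerate inputs are values, not crashes: days with <2 valid samples,
  bins with zero FVC variance or too few pixels, pixels with constant
  regressors or <10 complete years all propagate as flagged missing
  results; unit mismatches and unknown land-cover codes are rejected
  loudly.
- Missing NetCDF variables/units fail with the offending name; scene
  round trips are bit-exact for float64 fields.

## Problem sizes

Recovery and calibration tests run on 60×60-pixel scenes with 30 days of
96 daily samples (20 seeds), 1000-replicate null calibrations, and
500-pixel 19-year panels. These sizes put binomial noise on the checked
rates well inside the asserted bands while keeping the full suite under a
minute of compute for the heavy tests. A full-year (365-day) cube changes
nothing structurally — only the annual-mean noise floor.

## Known limitations

- No multiple-testing control across bins or pixels; coverage percentages
  inherit the per-test α.
- The all-vs-humid Welch test compares overlapping samples and is
  conservative; use the dry-vs-humid variant when nominal level matters.
- FVC clipping at [0, 1] slightly biases bins at the gradient extremes.
- The generator's discrete θ/R_S levels mean between-bin variation is
  confounded with the aridity gradient by design; gradient summaries on
  synthetic scenes read planted structure, not an emergent result.
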