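# Methods

## The diagnostic

topwet implements a diagnostic — not prognostic — wetland model in the
TOPMODEL tradition: the saturated part of a basin is wherever the compound
topographic index (CTI, $\ln(a/\tan\beta)$) exceeds a threshold set by the
basin-mean water-table depth. The full chain per basin and time step is

```
SM  --(saturation deficit)-->  WTD  --(threshold)-->  c*  --(CTI CDF)-->  f  -->  W = f·A
```

with

* `wtd = D · (1 − SM/SM_sat)`, clipped to `[0, D]`. The water table is
  diagnosed from the storage deficit of a fixed soil column; `D = 2 m`
  matches the 0–200 cm soil-moisture column, and
  `SM_sat = φ·ρ_w·D = 0.45 · 1000 · 2 = 900 kg/m²` with a configurable
  porosity `φ` (0.45 is a generic loamy value). Both `D` and `SM_sat` are
  parameters, not constants, so other column definitions or soils drop in
  without code changes.
* `c* = cti_mean + M · wtd`. This is the exponential-transmissivity
  TOPMODEL threshold relation; the integer decay parameter
  `M ∈ {1, …, 15}` controls how quickly saturation probability falls with
  water-table depth — larger `M` shrinks the wetland for the same depth.
  `M` is deliberately restricted to the 15 integer values and never
  refined continuously: the calibration target is a 15-point grid search
  by construction.
* `f = #{c_i ≥ c*} / n`, read off the basin's empirical CTI sample. The
  comparison is inclusive (a pixel exactly at the threshold is saturated).
  An optional cap `f_max ∈ (0, 1]` is supported but unset by default.

One WTD is computed per basin from basin-mean soil moisture (not per
pixel); the spatial disaggregation happens entirely through the CTI
distribution. A consequence worth knowing: at full saturation
(`wtd = 0`) the threshold equals the basin-mean CTI, so the maximal
diagnosed wetland is the share of pixels at or above the mean CTI — not
the whole basin — unless `f_max` or a degenerate CTI distribution says
otherwise. That is a property of the threshold relation, not a bug.

### Aggregation order

Soil moisture is averaged over each analysis window (a multi-year mapping
period for calibration, a calendar year for projection) *first*, and the
nonlinear chain is applied to the window mean — one area per window. The
alternative (monthly areas, then averaging) differs because the chain is
nonlinear; window-first matches calibrating against one wetland map per
period.

## Calibration

Per basin, the forward model is run at every `M ∈ {1..15}` over the
historical windows and compared with the observed (mapped) areas by RMSE
in km² (areas, not fractions, because the observation is an area).
The minimising `M` wins; exact ties break to the **smallest** `M` —
deterministic, and parsimonious in the sense of assuming the weakest
topographic control consistent with the data. Missing periods are dropped
from the RMSE (with the count recorded); all-NaN observations are an
error. Basins are independent, so the calibration table is
order-independent and trivially resumable.

## Projection and ensemble summaries

Calibrated `M` values are applied to annual-mean soil moisture of every
(model, scenario) member, giving an area cube over
(model, scenario, year, basin). Summaries:

* continental series = sum over basins; ensemble mean = unweighted
  arithmetic mean over models (no member weighting is attempted);
* net change between two years as a percent of the earlier year;
* agreement maps: basins are assigned to equal-angle grid cells
  (default 0.2°, anchored at integer degrees) by their **centroid**; per
  cell and member, the net change over the horizon is classified as loss
  (< −ε), gain (> +ε) or unchanged, and the three member counts are
  tallied. ε defaults to 1% of the cell's initial ensemble-mean wetland
  area — "unchanged" needs a tolerance to be meaningful, and a relative
  one treats large and small wetland cells even-handedly. The three
  counts always sum to the member count, and cellwise net changes sum
  exactly to the continental net change.

## Supporting statistics

* **Change ledger**: per-unit differences between two snapshots split into
  gross loss (sum of negative differences), gross gain (positive), net =
  gain − loss exactly, and percent of the base-year total. Both gross and
  net are exposed since either may be the quantity of interest.
  Percentages are reported to 2 decimal places.
* **Mann–Kendall**: `S = Σ_{i<j} sign(x_j − x_i)`, tie-corrected variance
  `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, ±1 continuity correction on `Z`,
  two-sided normal p. An all-tied series returns S=0, Z=0, p=1. The
  continuity correction makes the test slightly conservative for short
  series; the test suite checks the empirical type-I error on length-50
  white noise stays within 5% ± 1%.
* **Linear trend**: ordinary least squares on (time index, value) via
  `scipy.stats.linregress`; R² is the squared Pearson correlation
  (defined as 1 when the fit is exact, including the two-point case).
* **Grid-cell area**: spherical band formula
  `A = R²·Δλ·(sin φ_N − sin φ_S)` with `R = 6371 km`; a 0.2° equatorial
  cell is ≈ 494.6 km².
* **Accuracy assessment**: confusion matrix with **rows = reference,
  columns = mapped** (stated here because conventions differ); producer's
  accuracy = per-class recall, user's = per-class precision, overall =
  trace/total. Only the 30% validation split of the sample points is
  scored by default.

## The synthetic-data generator

The generator exists so that every stage is exercisable and testable
without any real data. What it emulates, and the defaults that define the
study conditions:

| knob | default | rationale |
|---|---|---|
| CTI pixels | Gamma(shape 4, scale 2) | right-skewed, positive, mean 8 — qualitatively like real CTI histograms |
| pixels per basin | 2000 | real basins carry 1e5–1e7 30-m CTI pixels; a large sample keeps the empirical upper tail dense enough to separate adjacent M thresholds |
| basins | 200 | the scale of the parameter-recovery experiment |
| models × scenarios | 14 × (SSP126, SSP245, SSP370, SSP585) | the ensemble design the pipeline targets |
| years | 1984–2100 monthly | historical calibration span plus projection horizon |
| soil moisture | `sm_sat·(0.55 + trend·t + 0.08·sin + N(0, 0.03))`, clipped to `[0, sm_sat]` | mid-range baseline, visible seasonality, modest monthly noise |
| trend | 0.02·sm_sat/decade × scenario multiplier (0.5, 1.0, 1.5, 2.0) | multipliers order the scenarios mild → severe; each pseudo-model perturbs baseline (sd 2%) and trend (sd 30%) for ensemble spread |
| observation noise | multiplicative lognormal, CV 0.05, mean 1 | areas are positive and classification error scales with extent |
| historical periods | 9 periods partitioning 1984–2021, ends 1984–1990 and 2019–2021 | the mapping cadence; the interior partition is a configurable default, never hard-coded |
| label noise | 10% symmetric, 70/30 train/validation split | typical interpretation-error and split design |

One designated "truth" model (the first model, first scenario) generates
the observed areas via the forward model under each basin's hidden true
`M`; the other members exist only to exercise ensemble spread. With zero
observation noise the generator is an exact closed loop with the forward
model, which is what makes noiseless calibration recovery an exact test.

All randomness flows from a single integer seed through fixed, named
sub-streams (basins / soil moisture / observations / sample points), so a
given product is byte-identical run to run and independent of which other
products are generated — this is also why skipping a pipeline stage does
not shift downstream draws.

What the generator does **not** emulate: spatial autocorrelation within
rasters, climate teleconnections or realistic inter-model covariance,
Landsat imagery or classification behaviour, coastal processes. Passing
tests therefore demonstrate the correctness and statistical behaviour of
the *method* under its stated assumptions, not the accuracy of any
real-world wetland map.

## Numerical and I/O choices

* Fractions come from `searchsorted` on the basin's sorted CTI sample —
  exact counting, no interpolation; tests verify exact agreement with a
  brute-force pixel loop.
* CSV floats are written as `%.17g` and parsed in round-trip mode, and
  NetCDF uses float64 via the netCDF3 (scipy) backend, so a pipeline whose
  stages run from files is bit-identical to one run in memory; the artifact
  manifest checksums (SHA-256) make this testable. Provenance headers
  carry the stage name and a hash of the scientific configuration
  (input-file paths excluded, timestamps only in logs, so checksums stay
  reproducible).
* Degenerate inputs: a point-mass CTI distribution yields fractions in
  {0, 1} and calibration ties resolve to `M = 1`; an empty aggregation
  window, a zero base area, a zero-variance time axis and an all-NaN
  observation vector are explicit errors, not NaNs.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes —
200 basins × 2000 pixels for parameter recovery, 50–60 basins with the
full 14 × 4 ensemble for projection demonstrations, 10,000 replicates for
the trend-test calibration — chosen so the whole suite completes in well
under a minute while every statistical check retains comfortable power.
All sizes are configuration, and the pipeline scales linearly in basins,
members and months.

## Known limitations

* The water-table relation is a linear storage-deficit diagnostic; no
  lateral routing, groundwater dynamics or within-window inundation
  seasonality.
* `M` is per-basin and temporally constant; no spatial regularisation
  across neighbouring basins and no uncertainty interval on `M`.
* Ensemble statistics treat members as exchangeable (unweighted mean).
* Accuracy assessment is the plain confusion matrix; error-adjusted area
  estimators (Olofsson-style) are out of scope.
* The basin→cell assignment is all-or-nothing by centroid; basins are not
  split across cell boundaries.
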