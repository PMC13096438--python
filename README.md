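# topwet

A tested, reusable implementation of the TOPMODEL-based wetland-extent
diagnostic used to assess historical change and project the future of
inland wetland area from soil moisture: forward model, per-basin
calibration, multi-model climate-scenario ensemble projection, and the
change-accounting / trend / map-accuracy statistics that summarise the
results. A built-in synthetic-data generator emulates every input, so the
whole pipeline runs and is tested without downloading any rasters or
climate cubes.

It is aimed at ecohydrologists and remote-sensing analysts who have (a) a
compound topographic index (CTI) distribution per drainage basin, (b)
basin-mean column soil moisture through time (e.g. a land data assimilation
product for the past, CMIP6 members for the future), and (c) mapped wetland
areas for a set of historical periods to calibrate against.

## The model

For a basin with land area $A$, CTI pixel sample $\{c_i\}$ with mean
$\bar c$, and column soil moisture $SM(t)$ (kg/m² over a 0–2 m column with
saturated content $SM_{sat}$):

1. **Water-table depth** from the saturation deficit,
   $\Gamma(t) = D\,(1 - SM(t)/SM_{sat})$, clipped to $[0, D]$, with column
   depth $D = 2$ m and $SM_{sat} = \phi\,\rho_w D$ (porosity $\phi = 0.45$
   by default, giving 900 kg/m²).
2. **CTI threshold** $c^*(t) = \bar c + M\,\Gamma(t)$, where the integer
   parameter $M \in \{1,\dots,15\}$ sets how fast saturation decays with
   water-table depth.
3. **Saturated (wetland) fraction**
   $f(t) = \#\{i : c_i \ge c^*(t)\} / \#\{i\}$ — pixels whose topography is
   convergent and flat enough to be saturated at that water table.
4. **Wetland area** $W(t) = f(t)\,A$ (km²).

The chain is monotone: wetter soil → shallower water table → lower
threshold → larger wetland. **Calibration** grid-searches $M$ per basin to
minimise the RMSE between simulated and observed wetland areas over the
historical mapping periods (ties go to the smallest $M$). **Projection**
applies the calibrated $M$ to annual-mean soil moisture from each
(climate model, scenario) member, yielding an area cube over
(model, scenario, year, basin), ensemble means, net-change percentages and
per-0.2°-cell counts of members agreeing on loss / gain / no change.
Supporting statistics include gross/net change ledgers, the Mann–Kendall
trend test (tie-corrected variance, continuity correction), OLS trend
lines, spherical grid-cell areas and confusion-matrix map accuracies
(producer's = recall, user's = precision).

## Worked example

```python
from topwet import (
    GeneratorConfig, generate_basins, generate_sm_cube, generate_observed_areas,
    default_historical_periods, sm_series_from_cube, calibrate_all,
    project, continental_series, ensemble_mean, net_change_pct, mann_kendall,
)

config = GeneratorConfig(n_basins=50, n_models=14, seed=42)
basins, true_m = generate_basins(config)           # hidden true M per basin
cube = generate_sm_cube(basins, config)            # (model, scenario, time, basin)

periods = default_historical_periods()             # 9 mapping periods, 1984-2021
obs = generate_observed_areas(basins, cube, periods, config, true_m)
sm_hist = {b.basin_id: sm_series_from_cube(cube, "model01", "SSP126", b.basin_id)
           for b in basins}
calib, _ = calibrate_all(basins, sm_hist, obs, periods)
recovered = (calib.set_index("basin_id")["M"] == true_m).mean()
print(f"M recovered exactly for {100 * recovered:.0f}% of {len(basins)} basins "
      f"(median RMSE {calib.rmse_km2.median():.1f} km2)")

area = project(basins, calib, cube)
mean = ensemble_mean(continental_series(area))
for s in area["scenario"].values:
    change = net_change_pct(mean.sel(scenario=s), 2023, 2100)
    mk = mann_kendall(mean.sel(scenario=s).to_series().loc[2023:].to_numpy())
    print(f"{s}: net change 2023-2100 = {change:+.1f}%  (Z = {mk.Z:.1f}, "
          f"p = {mk.p_two_sided:.1e})")
```

prints

```
M recovered exactly for 100% of 50 basins (median RMSE 4.8 km2)
SSP126: net change 2023-2100 = +27.0%  (Z = 12.9, p = 5.0e-38)
SSP245: net change 2023-2100 = +69.2%  (Z = 13.0, p = 2.3e-38)
SSP370: net change 2023-2100 = +119.4%  (Z = 13.0, p = 2.3e-38)
SSP585: net change 2023-2100 = +140.1%  (Z = 13.0, p = 2.3e-38)
```

Despite 5% multiplicative observation noise on the "mapped" areas, the
per-basin grid search recovers every hidden M exactly; the projected
ensemble-mean wetland area then rises monotonically with scenario severity
(the generator's soil-moisture trends are ordered SSP126 < … < SSP585), and
the Mann–Kendall test flags each upward trend as highly significant.

A command-line interface mirrors the stages
(`topwet simulate | calibrate | project | change | trends | accuracy | run`);
`topwet run --out-dir out/` executes everything and writes a checksummed
artifact manifest, reproducible bit-for-bit under a fixed seed.

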