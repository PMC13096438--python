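"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything downstream — calibration, ensemble projection, change accounting,
accuracy assessment — can be exercised without any real rasters or climate
cubes.  The generator emulates four input families:

* basins with heavy-right-tailed CTI pixel distributions (gamma-distributed
  pixels) and a hidden per-basin "true" M;
* monthly basin-mean soil-moisture trajectories for a set of pseudo climate
  models under several emission scenarios (baseline + scenario-ordered trend
  + seasonal sinusoid + white noise, clipped to the physical range);
* observed wetland areas for a set of historical mapping periods, produced
  by the forward diagnostic under each basin's hidden M from a designated
  "truth" model, with multiplicative lognormal observation noise;
* labelled sample points on a categorical map with symmetric label noise and
  a seeded 70/30 train/validation split.

All draws derive from a single integer seed; a fixed named sub-stream per
product keeps outputs byte-identical run to run and independent of which
other products are generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .core import BasinRecord, SoilMoistureSeries, simulate_area_series, M_MIN, M_MAX
from .errors import InvalidConfigError, RangeError

# fixed stream ids so skipping one stage never shifts another stage's draws
_STREAMS = {"basins": 1, "sm": 2, "obs": 3, "points": 4}

#: Default partition of 1984-2021 into 9 mapping periods.  The end members
#: (1984-1990, 2019-2021) follow the historical Landsat record; the interior
#: breaks are an even default and are fully configurable.
DEFAULT_HISTORICAL_PERIODS: tuple[tuple[int, int], ...] = (
    (1984, 1990),
    (1991, 1994),
    (1995, 1998),
    (1999, 2002),
    (2003, 2006),
    (2007, 2010),
    (2011, 2014),
    (2015, 2018),
    (2019, 2021),
)


def default_historical_periods() -> list[tuple[int, int]]:
    return [tuple(p) for p in DEFAULT_HISTORICAL_PERIODS]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named product under one master seed."""
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Soil-moisture structure is expressed as fractions of ``sm_sat`` (the
    saturated water content of the 0-2 m column, kg/m^2, default
    0.45 porosity x 1000 kg/m^3 x 2 m = 900).  Scenario trend multipliers
    order the scenarios from mild to severe forcing.
    """

    n_basins: int = 200
    pixels_per_basin: int = 2000
    cti_shape: float = 4.0
    cti_scale: float = 2.0
    basin_area_km2_range: tuple[float, float] = (50.0, 5000.0)
    n_models: int = 14
    scenarios: tuple[str, ...] = ("SSP126", "SSP245", "SSP370", "SSP585")
    scenario_trend_multipliers: tuple[float, ...] | None = None
    year_range: tuple[int, int] = (1984, 2100)
    sm_sat: float = 900.0
    column_depth_m: float = 2.0
    sm_baseline_frac: float = 0.55
    sm_trend_frac_per_decade: float = 0.02
    sm_seasonal_amp_frac: float = 0.08
    sm_noise_sd_frac: float = 0.03
    model_baseline_sd: float = 0.02
    model_trend_sd: float = 0.30
    true_M_range: tuple[int, int] = (1, 15)
    obs_noise_cv: float = 0.05
    label_error_rate: float = 0.10
    n_sample_points: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_basins", "pixels_per_basin", "n_models", "n_sample_points"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.cti_shape <= 0 or self.cti_scale <= 0:
            raise InvalidConfigError("gamma CTI parameters must be positive")
        lo, hi = self.basin_area_km2_range
        if not 0 < lo <= hi:
            raise InvalidConfigError("basin_area_km2_range must be positive and ordered")
        if len(self.scenarios) < 1:
            raise InvalidConfigError("at least one scenario required")
        if self.scenario_trend_multipliers is not None and len(
            self.scenario_trend_multipliers
        ) != len(self.scenarios):
            raise InvalidConfigError("one trend multiplier per scenario required")
        y0, y1 = self.year_range
        if y1 < y0:
            raise InvalidConfigError("year_range must be ordered")
        if self.sm_sat <= 0 or self.column_depth_m <= 0:
            raise InvalidConfigError("sm_sat and column_depth_m must be positive")
        for name in (
            "sm_baseline_frac",
            "sm_trend_frac_per_decade",
            "sm_seasonal_amp_frac",
            "sm_noise_sd_frac",
            "label_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        m_lo, m_hi = self.true_M_range
        if not (M_MIN <= m_lo <= m_hi <= M_MAX):
            raise InvalidConfigError(
                f"true_M_range must be within [{M_MIN}, {M_MAX}] and ordered"
            )
        if self.obs_noise_cv < 0:
            raise InvalidConfigError("obs_noise_cv must be >= 0")

    @property
    def trend_multipliers(self) -> np.ndarray:
        if self.scenario_trend_multipliers is not None:
            return np.asarray(self.scenario_trend_multipliers, dtype=float)
        if len(self.scenarios) == 1:
            return np.ones(1)
        return np.linspace(0.5, 2.0, len(self.scenarios))

    @property
    def model_names(self) -> list[str]:
        return [f"model{i + 1:02d}" for i in range(self.n_models)]

    def to_dict(self) -> dict:
        return asdict(self)


def generate_basins(config: GeneratorConfig) -> tuple[list[BasinRecord], pd.Series]:
    """Draw basins with gamma-distributed CTI pixels and hidden true M.

    Returns the basin records and a Series of the hidden per-basin M values
    (the calibration "truth" kept separate for recovery experiments).
    Centroids are drawn uniformly over an Africa-like lat/lon box and only
    feed the 0.2-degree grid-cell assignment.
    """
    config.validate()
    rng = stream_rng(config.seed, "basins")
    lo, hi = config.basin_area_km2_range
    m_lo, m_hi = config.true_M_range
    basins: list[BasinRecord] = []
    true_m = {}
    for i in range(config.n_basins):
        bid = f"basin{i + 1:05d}"
        cti = rng.gamma(config.cti_shape, config.cti_scale, config.pixels_per_basin)
        basins.append(
            BasinRecord(
                basin_id=bid,
                area_km2=float(rng.uniform(lo, hi)),
                cti_values=cti,
                lat=float(rng.uniform(-35.0, 35.0)),
                lon=float(rng.uniform(-17.0, 50.0)),
            )
        )
        true_m[bid] = int(rng.integers(m_lo, m_hi + 1))
    return basins, pd.Series(true_m, name="true_M")


def generate_sm_cube(
    basins: Sequence[BasinRecord], config: GeneratorConfig
) -> xr.DataArray:
    """Monthly soil-moisture cube with dims (model, scenario, time, basin).

    Each series is ``sm_sat * (baseline + trend*t + seasonal + noise)``
    clipped to [0, sm_sat].  Scenario trend magnitudes follow the configured
    multipliers; each pseudo-model perturbs the shared baseline and trend so
    the ensemble has spread.
    """
    if not basins:
        raise InvalidConfigError("basins must be non-empty")
    config.validate()
    rng = stream_rng(config.seed, "sm")
    y0, y1 = config.year_range
    times = pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")
    n_t = len(times)
    t_years = np.arange(n_t) / 12.0
    month = times.month.to_numpy()
    seasonal = config.sm_seasonal_amp_frac * np.sin(2 * np.pi * (month - 1) / 12.0)

    n_m, n_s, n_b = config.n_models, len(config.scenarios), len(basins)
    base_factor = 1.0 + config.model_baseline_sd * rng.standard_normal(n_m)
    trend_factor = 1.0 + config.model_trend_sd * rng.standard_normal(n_m)
    mult = config.trend_multipliers

    frac = np.empty((n_m, n_s, n_t, n_b))
    trend_per_year = config.sm_trend_frac_per_decade / 10.0
    for i in range(n_m):
        for j in range(n_s):
            drift = (
                config.sm_baseline_frac * base_factor[i]
                + trend_per_year * mult[j] * trend_factor[i] * t_years
                + seasonal
            )
            noise = config.sm_noise_sd_frac * rng.standard_normal((n_t, n_b))
            frac[i, j] = drift[:, None] + noise
    values = np.clip(config.sm_sat * frac, 0.0, config.sm_sat)

    if (values.sum(axis=2) == 0.0).any():
        warnings.warn(
            "clipping produced at least one all-zero soil-moisture series",
            stacklevel=2,
        )

    return xr.DataArray(
        values,
        dims=("model", "scenario", "time", "basin"),
        coords={
            "model": config.model_names,
            "scenario": list(config.scenarios),
            "time": times,
            "basin": [b.basin_id for b in basins],
        },
        name="soil_moisture",
        attrs={
            "units": "kg m-2",
            "sm_sat": config.sm_sat,
            "column_depth_m": config.column_depth_m,
        },
    )


def sm_series_from_cube(
    cube: xr.DataArray, model: str, scenario: str, basin_id: str
) -> SoilMoistureSeries:
    """Extract one (model, scenario, basin) trajectory as a typed series."""
    da = cube.sel(model=model, scenario=scenario, basin=basin_id)
    return SoilMoistureSeries(
        times=pd.DatetimeIndex(da["time"].values),
        values=da.values,
        sm_sat=float(cube.attrs["sm_sat"]),
        column_depth_m=float(cube.attrs.get("column_depth_m", 2.0)),
    )


def generate_observed_areas(
    basins: Sequence[BasinRecord],
    sm_cube: xr.DataArray,
    historical_periods: Sequence[tuple[int, int]],
    config: GeneratorConfig,
    true_m: pd.Series,
    truth_model: str | None = None,
    truth_scenario: str | None = None,
) -> pd.DataFrame:
    """Observed wetland areas per basin and mapping period.

    The forward diagnostic is run with each basin's hidden true M on
    period-mean soil moisture from one designated "truth" model (default:
    the first model and scenario in the cube), then multiplied by lognormal
    noise with coefficient of variation ``obs_noise_cv`` (mean-one, so zero
    CV reproduces the forward model exactly).  The noise-free truth area is
    kept in a ``true_area_km2`` column for closed-loop tests.
    """
    config.validate()
    years = pd.DatetimeIndex(sm_cube["time"].values).year
    y_lo, y_hi = int(years.min()), int(years.max())
    for start, end in historical_periods:
        if start < y_lo or end > y_hi:
            raise RangeError(
                f"period {start}-{end} outside soil-moisture years {y_lo}-{y_hi}"
            )
    truth_model = truth_model or str(sm_cube["model"].values[0])
    truth_scenario = truth_scenario or str(sm_cube["scenario"].values[0])
    rng = stream_rng(config.seed, "obs")

    cv = config.obs_noise_cv
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for basin in basins:
        sm = sm_series_from_cube(sm_cube, truth_model, truth_scenario, basin.basin_id)
        truth = simulate_area_series(
            basin, int(true_m[basin.basin_id]), sm, list(historical_periods)
        )
        if cv > 0:
            # mean-one lognormal multiplier with the requested CV
            noise = rng.lognormal(-0.5 * sigma**2, sigma, len(truth))
        else:
            noise = np.ones(len(truth))
        for (label, area), eps, (start, end) in zip(
            truth.items(), noise, historical_periods
        ):
            rows.append(
                {
                    "basin_id": basin.basin_id,
                    "period": label,
                    "year_start": start,
                    "year_end": end,
                    "area_km2": float(area * eps),
                    "true_area_km2": float(area),
                }
            )
    return pd.DataFrame(rows)


def generate_sample_points(
    truth_map: np.ndarray,
    config: GeneratorConfig,
    n_points: int | None = None,
) -> pd.DataFrame:
    """Labelled sample points on a categorical map with label noise.

    Each point carries the reference label read from the map and a mapped
    label equal to it with probability ``1 - label_error_rate`` (otherwise a
    uniformly random *other* class), plus a seeded 70/30 train/validation
    split flag.
    """
    config.validate()
    truth_map = np.asarray(truth_map)
    if truth_map.ndim != 2:
        raise InvalidConfigError("truth_map must be a 2-D categorical array")
    classes = np.unique(truth_map)
    if classes.size < 2 and config.label_error_rate > 0:
        raise InvalidConfigError(
            "label noise needs at least two classes in the truth map"
        )
    n = int(n_points if n_points is not None else config.n_sample_points)
    rng = stream_rng(config.seed, "points")
    rows_idx = rng.integers(0, truth_map.shape[0], n)
    cols_idx = rng.integers(0, truth_map.shape[1], n)
    reference = truth_map[rows_idx, cols_idx]

    mapped = reference.copy()
    flip = rng.random(n) < config.label_error_rate
    if flip.any():
        # uniformly among the other classes: shift by 1..k-1 in class rank
        rank = np.searchsorted(classes, reference[flip])
        shift = rng.integers(1, classes.size, flip.sum())
        mapped[flip] = classes[(rank + shift) % classes.size]

    split = np.where(rng.random(n) < 0.7, "train", "val")
    return pd.DataFrame(
        {
            "point_id": np.arange(n),
            "row": rows_idx,
            "col": cols_idx,
            "reference": reference,
            "mapped": mapped,
            "split": split,
        }
    )
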