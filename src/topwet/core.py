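"""TOPMODEL-style wetland-extent diagnostic.

The forward chain maps basin-mean column soil moisture to a wetland area in
four steps:

1. water-table depth (WTD) from the column saturation deficit,
   ``wtd = D * (1 - SM / SM_sat)`` with column depth ``D`` (default 2 m);
2. a compound-topographic-index (CTI) threshold from the basin-mean CTI,
   the transmissivity-decay parameter ``M`` and the WTD,
   ``cti* = cti_mean + M * wtd``;
3. the saturated (wetland) fraction as the share of basin pixels whose CTI
   is at or above the threshold, read off the basin's empirical CTI
   distribution;
4. wetland area as fraction times basin land area.

Larger ``M`` means saturation decays faster with depth: the threshold rises
and the diagnosed wetland shrinks for the same water table.  The chain is
monotone: wetter soil -> shallower water table -> lower threshold -> larger
wetland fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, RangeError

M_MIN, M_MAX = 1, 15

__all__ = [
    "M_MIN",
    "M_MAX",
    "BasinRecord",
    "SoilMoistureSeries",
    "WTDSeries",
    "wtd_from_sm",
    "wtd_from_moisture",
    "cti_threshold",
    "wetland_fraction",
    "basin_wetland_area",
    "simulate_area_series",
    "window_mean_sm",
]


@dataclass
class BasinRecord:
    """A drainage basin with its empirical CTI distribution.

    Parameters
    ----------
    basin_id : str
        Stable identifier.
    area_km2 : float
        Basin land area, km^2; must be positive.
    cti_values : np.ndarray
        Dimensionless CTI pixel values (non-empty).
    cti_mean : float, optional
        Mean CTI; computed from ``cti_values`` when omitted, validated
        against them (1e-9 relative tolerance) when given.
    lat, lon : float, optional
        Centroid coordinates in degrees, used only for grid-cell assignment.
    f_max : float, optional
        Cap on the wetland fraction, in (0, 1]; unset means no cap.
    """

    basin_id: str
    area_km2: float
    cti_values: np.ndarray
    cti_mean: float | None = None
    lat: float | None = None
    lon: float | None = None
    f_max: float | None = None
    _cti_sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cti_values = np.asarray(self.cti_values, dtype=float)
        if self.cti_values.size == 0:
            raise InvalidParameterError(f"basin {self.basin_id}: empty CTI sample")
        if not self.area_km2 > 0:
            raise InvalidParameterError(
                f"basin {self.basin_id}: area_km2 must be > 0, got {self.area_km2}"
            )
        mean = float(np.mean(self.cti_values))
        if self.cti_mean is None:
            self.cti_mean = mean
        elif abs(self.cti_mean - mean) > 1e-9 * max(1.0, abs(mean)):
            raise InvalidParameterError(
                f"basin {self.basin_id}: cti_mean {self.cti_mean} inconsistent "
                f"with mean of cti_values {mean}"
            )
        if self.f_max is not None and not 0.0 < self.f_max <= 1.0:
            raise InvalidParameterError(
                f"basin {self.basin_id}: f_max must be in (0, 1], got {self.f_max}"
            )
        self._cti_sorted = np.sort(self.cti_values)

    @property
    def n_pixels(self) -> int:
        return self.cti_values.size


@dataclass
class SoilMoistureSeries:
    """Basin-mean column soil moisture over time, kg/m^2 for a 0-2 m column."""

    times: pd.DatetimeIndex
    values: np.ndarray
    sm_sat: float
    column_depth_m: float = 2.0

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times),):
            raise InvalidParameterError(
                f"times ({len(self.times)}) and values ({self.values.shape}) disagree"
            )
        if not self.sm_sat > 0:
            raise InvalidParameterError(f"sm_sat must be > 0, got {self.sm_sat}")
        if not self.column_depth_m > 0:
            raise InvalidParameterError(
                f"column_depth_m must be > 0, got {self.column_depth_m}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > self.sm_sat * (1 + 1e-9)):
            raise InvalidParameterError(
                f"soil moisture outside [0, sm_sat={self.sm_sat}]: "
                f"range [{finite.min()}, {finite.max()}]"
            )


@dataclass
class WTDSeries:
    """Water-table depth below the surface, metres; 0 = fully saturated."""

    times: pd.DatetimeIndex
    wtd_m: np.ndarray
    column_depth_m: float = 2.0


def wtd_from_moisture(
    sm_values: np.ndarray | float, sm_sat: float, column_depth_m: float = 2.0
) -> np.ndarray | float:
    """WTD from the column saturation deficit: ``D * (1 - sm/sm_sat)``.

    Values are clipped to [0, D].  Elementwise; accepts scalars or arrays.
    """
    if not sm_sat > 0:
        raise InvalidParameterError(f"sm_sat must be > 0, got {sm_sat}")
    wtd = column_depth_m * (1.0 - np.asarray(sm_values, dtype=float) / sm_sat)
    wtd = np.clip(wtd, 0.0, column_depth_m)
    return float(wtd) if np.ndim(wtd) == 0 else wtd


def wtd_from_sm(sm: SoilMoistureSeries) -> WTDSeries:
    """Convert a soil-moisture series to a water-table-depth series."""
    wtd = wtd_from_moisture(sm.values, sm.sm_sat, sm.column_depth_m)
    return WTDSeries(times=sm.times, wtd_m=wtd, column_depth_m=sm.column_depth_m)


def cti_threshold(
    cti_mean: float, m: int, wtd_m: np.ndarray | float
) -> np.ndarray | float:
    """CTI saturation threshold ``cti* = cti_mean + M * wtd``.

    Nondecreasing in both M and WTD; at the surface (wtd = 0) every M gives
    the basin-mean CTI.
    """
    if not M_MIN <= m <= M_MAX:
        raise InvalidParameterError(f"M must be in [{M_MIN}, {M_MAX}], got {m}")
    wtd = np.asarray(wtd_m, dtype=float)
    if np.any(wtd < -1e-12):
        raise InvalidParameterError("wtd_m must be >= 0")
    out = cti_mean + m * wtd
    return float(out) if np.ndim(wtd_m) == 0 else out


def wetland_fraction(
    basin: BasinRecord, cti_star: np.ndarray | float
) -> np.ndarray | float:
    """Fraction of basin pixels with CTI >= ``cti_star`` (inclusive).

    Uses the basin's sorted empirical CTI sample; capped at ``basin.f_max``
    if set.  Vectorised over ``cti_star``.
    """
    star = np.asarray(cti_star, dtype=float)
    n = basin.n_pixels
    # 'left' gives the first index with cti >= star, so n - idx counts the
    # inclusive exceedance.
    idx = np.searchsorted(basin._cti_sorted, star, side="left")
    f = (n - idx) / n
    if basin.f_max is not None:
        f = np.minimum(f, basin.f_max)
    return float(f) if np.ndim(cti_star) == 0 else f


def basin_wetland_area(basin: BasinRecord, f: np.ndarray | float) -> np.ndarray | float:
    """Wetland area in km^2: fraction times basin land area."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > 1):
        raise InvalidParameterError("wetland fraction must lie in [0, 1]")
    area = f_arr * basin.area_km2
    return float(area) if np.ndim(f) == 0 else area


def window_mean_sm(
    sm: SoilMoistureSeries,
    aggregation: str | Sequence[tuple[int, int]],
) -> tuple[list[str], np.ndarray]:
    """Mean soil moisture per aggregation window.

    ``aggregation`` is either ``"annual"`` or a list of inclusive
    ``(start_year, end_year)`` tuples.  Returns window labels and the
    window-mean values; an empty window raises :class:`RangeError`.
    """
    years = sm.times.year.to_numpy()
    if isinstance(aggregation, str):
        if aggregation != "annual":
            raise InvalidParameterError(f"unknown aggregation {aggregation!r}")
        uniq = np.unique(years)
        labels = [str(int(y)) for y in uniq]
        means = np.array([sm.values[years == y].mean() for y in uniq])
        return labels, means
    labels, means = [], []
    for start, end in aggregation:
        mask = (years >= start) & (years <= end)
        if not mask.any():
            raise RangeError(f"window {start}-{end} is empty for this series")
        labels.append(f"{start}-{end}")
        means.append(sm.values[mask].mean())
    return labels, np.asarray(means)


def simulate_area_series(
    basin: BasinRecord,
    m: int,
    sm: SoilMoistureSeries,
    aggregation: str | Sequence[tuple[int, int]] = "annual",
) -> pd.Series:
    """Wetland-area series for one basin and one M.

    Soil moisture is averaged over each window first, then pushed through
    the nonlinear WTD -> threshold -> fraction chain (one area per window).
    Returns a Series of km^2 indexed by window label.
    """
    labels, sm_mean = window_mean_sm(sm, aggregation)
    wtd = wtd_from_moisture(sm_mean, sm.sm_sat, sm.column_depth_m)
    star = cti_threshold(basin.cti_mean, m, wtd)
    f = wetland_fraction(basin, star)
    area = basin_wetland_area(basin, f)
    return pd.Series(np.atleast_1d(area), index=labels, name=basin.basin_id)
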