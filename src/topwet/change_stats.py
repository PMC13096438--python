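"""Change accounting, trend tests, grid geometry and map accuracy.

Descriptive machinery for wetland-change analysis:

* a change ledger splitting per-unit area differences into gross loss,
  gross gain and their net, with the percent change against the base year;
* the Mann-Kendall nonparametric monotone-trend test (tie-corrected
  variance, continuity correction, two-sided normal p-value) and ordinary
  least-squares linear trend fitting;
* spherical areas of equal-angle grid cells;
* zonal driver time series over a mask, with Pearson correlation against an
  area series;
* confusion-matrix accuracy assessment (rows = reference, columns = mapped;
  producer's accuracy = per-class recall, user's accuracy = per-class
  precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    MissingDataError,
    ValidationError,
)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "ChangeLedger",
    "TrendResult",
    "ConfusionMatrix",
    "change_ledger",
    "mann_kendall",
    "linear_trend",
    "grid_cell_area",
    "zonal_driver_series",
    "accuracy_assessment",
    "confusion_from_counts",
]


@dataclass(frozen=True)
class ChangeLedger:
    """Gross and net area change between two snapshots, km^2."""

    gross_loss_km2: float
    gross_gain_km2: float
    net_change_km2: float
    base_area_km2: float
    pct_change: float


@dataclass
class TrendResult:
    """Trend statistics; Mann-Kendall fields and/or linear-fit fields."""

    S: int | None = None
    Z: float | None = None
    p_two_sided: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None


@dataclass
class ConfusionMatrix:
    """Reference-by-mapped counts with the standard accuracy measures (%)."""

    counts: pd.DataFrame  # rows = reference, columns = mapped
    producer_accuracy: pd.Series
    user_accuracy: pd.Series
    overall_accuracy: float

    @property
    def classes(self) -> list:
        return list(self.counts.index)


def change_ledger(area_t0: pd.Series, area_t1: pd.Series) -> ChangeLedger:
    """Partition per-unit area differences into gross loss, gain and net.

    The two tables must share an index (basins, cells or classes) and hold
    non-negative areas.  Net = gain - loss exactly; percent change is
    relative to the total base-year area.
    """
    t0, t1 = pd.Series(area_t0, dtype=float), pd.Series(area_t1, dtype=float)
    if set(t0.index) != set(t1.index):
        raise ValidationError("area tables cover different units")
    if (t0 < 0).any() or (t1 < 0).any():
        raise ValidationError("areas must be non-negative")
    diff = t1.reindex(t0.index) - t0
    loss = float(-diff[diff < 0].sum())
    gain = float(diff[diff > 0].sum())
    base = float(t0.sum())
    net = gain - loss
    pct = 100.0 * net / base if base > 0 else float("nan")
    return ChangeLedger(loss, gain, net, base, pct)


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall monotone-trend test.

    S sums the signs of all time-ordered pairwise differences; its variance
    uses the tie correction, Z applies the +/-1 continuity correction, and
    the p-value is two-sided normal.  An all-tied series returns
    S = 0, Z = 0, p = 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise InvalidParameterError(f"Mann-Kendall needs n >= 3, got {n}")
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    if var_s <= 0:  # every value tied
        return TrendResult(S=0, Z=0.0, p_two_sided=1.0)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(S=s, Z=float(z), p_two_sided=float(p))


def linear_trend(series, t=None) -> TrendResult:
    """Ordinary least-squares line through (time index, value).

    ``t`` defaults to 0..n-1; R^2 is the squared Pearson correlation.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise InvalidParameterError(f"linear trend needs n >= 2, got {y.size}")
    t = np.arange(y.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    if np.ptp(t) == 0:
        raise DegenerateInputError("time axis has zero variance")
    fit = stats.linregress(t, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 1.0
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2)


def grid_cell_area(lat_south: float, cell_deg: float) -> float:
    """Spherical area (km^2) of an equal-angle cell with its south edge at
    ``lat_south``: A = R^2 * dlon * (sin(lat_n) - sin(lat_s)), R = 6371 km."""
    if not -90.0 <= lat_south <= 90.0 or lat_south + cell_deg > 90.0 + 1e-12:
        raise InvalidParameterError(f"cell [{lat_south}, {lat_south + cell_deg}] off the sphere")
    lat_n = np.radians(min(lat_south + cell_deg, 90.0))
    lat_s = np.radians(lat_south)
    return float(
        EARTH_RADIUS_KM**2 * np.radians(cell_deg) * (np.sin(lat_n) - np.sin(lat_s))
    )


def zonal_driver_series(
    driver: np.ndarray,
    mask: np.ndarray,
    area_series=None,
) -> tuple[pd.Series, float | None]:
    """Masked spatial mean of a driver field per time window.

    ``driver`` has shape (n_windows, ny, nx) and ``mask`` (ny, nx); the
    result is the mean over masked pixels per window.  When an area series
    of equal length is supplied, its Pearson correlation with the zonal
    means is returned as well.
    """
    driver = np.asarray(driver, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if driver.ndim != 3 or driver.shape[1:] != mask.shape:
        raise ValidationError(
            f"driver {driver.shape} and mask {mask.shape} are not aligned"
        )
    if not mask.any():
        raise MissingDataError("empty mask")
    means = pd.Series(driver[:, mask].mean(axis=1), name="zonal_mean")
    r = None
    if area_series is not None:
        area = np.asarray(area_series, dtype=float)
        if area.size != means.size:
            raise ValidationError("area series length differs from window count")
        r = float(stats.pearsonr(means.to_numpy(), area).statistic)
    return means, r


def confusion_from_counts(counts: pd.DataFrame) -> ConfusionMatrix:
    """Accuracy measures from a reference-by-mapped count table."""
    counts = counts.astype(int)
    diag = pd.Series(np.diag(counts.reindex(columns=counts.index, fill_value=0)),
                     index=counts.index)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0).reindex(counts.index, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = 100.0 * diag / row_sums
        ua = 100.0 * diag / col_sums
    overall = 100.0 * diag.sum() / counts.to_numpy().sum()
    return ConfusionMatrix(
        counts=counts,
        producer_accuracy=pa.rename("producer_accuracy_pct"),
        user_accuracy=ua.rename("user_accuracy_pct"),
        overall_accuracy=float(overall),
    )


def accuracy_assessment(
    samples: pd.DataFrame,
    cat_map: np.ndarray | None = None,
    split: str | None = "val",
) -> ConfusionMatrix:
    """Confusion matrix from labelled sample points.

    Only the validation split is used when a ``split`` column is present
    (pass ``split=None`` to use all points).  Mapped labels come from the
    ``mapped`` column, or are read off ``cat_map`` at (row, col) when that
    column is absent; off-map points are dropped and reported in
    ``counts.attrs['off_map']``.
    """
    df = samples
    if split is not None and "split" in df.columns:
        df = df[df["split"] == split]
    if "reference" not in df.columns:
        raise ValidationError("samples need a 'reference' column")
    off_map: list[int] = []
    if "mapped" in df.columns:
        mapped = df["mapped"]
        reference = df["reference"]
    else:
        if cat_map is None:
            raise ValidationError("no 'mapped' column and no map supplied")
        cat_map = np.asarray(cat_map)
        r = df["row"].to_numpy()
        c = df["col"].to_numpy()
        ok = (r >= 0) & (r < cat_map.shape[0]) & (c >= 0) & (c < cat_map.shape[1])
        off_map = df.index[~ok].tolist()
        df = df[ok]
        mapped = pd.Series(cat_map[df["row"], df["col"]], index=df.index)
        reference = df["reference"]
    if len(df) == 0:
        raise MissingDataError("no usable sample points")
    classes = sorted(set(reference) | set(mapped))
    counts = (
        pd.crosstab(reference, mapped)
        .reindex(index=classes, columns=classes, fill_value=0)
        .rename_axis(index="reference", columns="mapped")
    )
    cm = confusion_from_counts(counts)
    cm.counts.attrs["off_map"] = off_map
    return cm
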