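"""Ensemble projection of wetland area under climate scenarios.

Calibrated per-basin M values are applied to annual-mean soil moisture from
every (model, scenario) member, giving a wetland-area cube indexed by
(model, scenario, year, basin).  On top of the cube sit the ensemble
summaries the analysis needs: continental sums, unweighted ensemble means,
net-change percentages between two years, and per-grid-cell counts of
ensemble members agreeing on loss / gain / no change.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .core import (
    BasinRecord,
    basin_wetland_area,
    cti_threshold,
    wetland_fraction,
    wtd_from_moisture,
)
from .errors import (
    InvalidParameterError,
    MissingDataError,
    RangeError,
    UndefinedPercentError,
)

__all__ = [
    "project",
    "continental_series",
    "ensemble_mean",
    "net_change_pct",
    "assign_cells",
    "cell_south_west",
    "agreement_map",
]


def _m_lookup(calib: pd.DataFrame | Mapping[str, int]) -> Mapping[str, int]:
    if isinstance(calib, pd.DataFrame):
        return dict(zip(calib["basin_id"], calib["M"].astype(int)))
    return calib


def project(
    basins: Sequence[BasinRecord],
    calib: pd.DataFrame | Mapping[str, int],
    sm_cube: xr.DataArray,
    scenarios: Sequence[str] | None = None,
    years: tuple[int, int] | None = None,
) -> xr.DataArray:
    """Wetland-area cube (model, scenario, year, basin) in km^2.

    Monthly soil moisture is averaged to annual means first, then pushed
    through the diagnostic chain with each basin's calibrated M.  Requested
    scenarios absent from the cube are skipped with a warning; basins
    without a calibration entry raise :class:`MissingDataError`.
    """
    m_of = _m_lookup(calib)
    missing = [b.basin_id for b in basins if b.basin_id not in m_of]
    if missing:
        raise MissingDataError(f"basins without calibration: {missing[:5]}...")

    available = [str(s) for s in sm_cube["scenario"].values]
    if scenarios is None:
        scenarios = available
    else:
        dropped = [s for s in scenarios if s not in available]
        if dropped:
            warnings.warn(f"scenarios not in cube, skipped: {dropped}", stacklevel=2)
        scenarios = [s for s in scenarios if s in available]
        if not scenarios:
            raise InvalidParameterError("no requested scenario present in cube")

    cube = sm_cube.sel(scenario=list(scenarios))
    annual = cube.groupby("time.year").mean("time")  # (model, scenario, year, basin)
    annual = annual.transpose("model", "scenario", "year", "basin")
    if years is not None:
        y0, y1 = years
        have = annual["year"].values
        if y0 < have.min() or y1 > have.max():
            raise RangeError(f"requested years {y0}-{y1} outside cube {have.min()}-{have.max()}")
        annual = annual.sel(year=slice(y0, y1))

    sm_sat = float(sm_cube.attrs["sm_sat"])
    depth = float(sm_cube.attrs.get("column_depth_m", 2.0))
    wtd = wtd_from_moisture(annual.values, sm_sat, depth)

    basin_ids = [str(b) for b in annual["basin"].values]
    by_id = {b.basin_id: b for b in basins}
    area = np.empty_like(wtd)
    for k, bid in enumerate(basin_ids):
        basin = by_id[bid]
        star = cti_threshold(basin.cti_mean, m_of[bid], wtd[..., k])
        area[..., k] = basin_wetland_area(basin, wetland_fraction(basin, star))

    return xr.DataArray(
        area,
        dims=annual.dims,
        coords=annual.coords,
        name="wetland_area",
        attrs={"units": "km2"},
    )


def continental_series(area_cube: xr.DataArray) -> xr.DataArray:
    """Total wetland area summed over basins, per (model, scenario, year)."""
    return area_cube.sum("basin")


def ensemble_mean(area_cube: xr.DataArray) -> xr.DataArray:
    """Unweighted arithmetic mean across ensemble members."""
    return area_cube.mean("model")


def net_change_pct(series, year0: int, year1: int) -> float:
    """Percent net change of an area series between two years.

    ``100 * (A(year1) - A(year0)) / A(year0)``; a zero base raises
    :class:`UndefinedPercentError`.
    """
    if isinstance(series, xr.DataArray):
        series = series.to_series()
    try:
        a0, a1 = float(series.loc[year0]), float(series.loc[year1])
    except KeyError as exc:
        raise RangeError(f"year {exc} not in series") from exc
    if a0 == 0:
        raise UndefinedPercentError(f"zero base area in {year0}")
    return 100.0 * (a1 - a0) / a0


def assign_cells(
    basins: Sequence[BasinRecord], cell_deg: float = 0.2
) -> tuple[pd.Series, list[str]]:
    """Assign each basin to an equal-angle grid cell by its centroid.

    Cells are anchored at integer degrees (cell index = floor(coord/cell)).
    Basins without a centroid go to an exceptions list, not an error.
    """
    mapping, exceptions = {}, []
    for b in basins:
        if b.lat is None or b.lon is None:
            exceptions.append(f"{b.basin_id}: no centroid")
            continue
        iy = int(np.floor(b.lat / cell_deg))
        ix = int(np.floor(b.lon / cell_deg))
        mapping[b.basin_id] = f"r{iy}c{ix}"
    return pd.Series(mapping, name="cell_id"), exceptions


def cell_south_west(cell_id: str, cell_deg: float = 0.2) -> tuple[float, float]:
    """South-west corner (lat, lon) of a cell id produced by assign_cells."""
    iy, ix = cell_id[1:].split("c")
    return float(int(iy) * cell_deg), float(int(ix) * cell_deg)


def agreement_map(
    area_cube: xr.DataArray,
    cell_assignment: pd.Series,
    year0: int,
    year1: int,
    epsilon_km2: float | None = None,
    epsilon_frac: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell counts of ensemble members agreeing on loss / gain / no change.

    ``area_cube`` must hold a single scenario with dims (model, year, basin).
    A member's cell is a loss if its net change over [year0, year1] is below
    -epsilon, a gain above +epsilon, else unchanged.  When ``epsilon_km2``
    is not given, epsilon is ``epsilon_frac`` of the cell's initial
    ensemble-mean wetland area.  Returns (agreement table, per-model net
    change table); basins absent from the assignment are listed in
    ``agreement.attrs['unassigned_basins']``.
    """
    if "scenario" in area_cube.dims:
        if area_cube.sizes["scenario"] != 1:
            raise InvalidParameterError("select one scenario before agreement_map")
        area_cube = area_cube.squeeze("scenario")
    if epsilon_km2 is not None and epsilon_km2 < 0:
        raise InvalidParameterError("epsilon_km2 must be >= 0")

    basin_ids = [str(b) for b in area_cube["basin"].values]
    unassigned = [b for b in basin_ids if b not in cell_assignment.index]
    keep = [b for b in basin_ids if b in cell_assignment.index]
    if not keep:
        raise MissingDataError("no basin has a cell assignment")
    cube = area_cube.sel(basin=keep)

    models = [str(m) for m in cube["model"].values]
    a0 = pd.DataFrame(cube.sel(year=year0).values, index=models, columns=keep)
    a1 = pd.DataFrame(cube.sel(year=year1).values, index=models, columns=keep)
    cells = cell_assignment.loc[keep]
    net_by_model = (a1 - a0).T.groupby(cells).sum().T  # models x cells
    a0_cells = a0.T.groupby(cells).sum().T

    if epsilon_km2 is not None:
        eps = pd.Series(epsilon_km2, index=net_by_model.columns)
    else:
        eps = epsilon_frac * a0_cells.mean(axis=0)

    loss = net_by_model.lt(-eps, axis=1)
    gain = net_by_model.gt(eps, axis=1)
    agreement = pd.DataFrame(
        {
            "n_loss": loss.sum(axis=0),
            "n_gain": gain.sum(axis=0),
            "n_unchanged": (~loss & ~gain).sum(axis=0),
            "net_change_mean_km2": net_by_model.mean(axis=0),
            "epsilon_km2": eps,
        }
    )
    agreement.index.name = "cell_id"
    agreement.attrs["unassigned_basins"] = unassigned
    return agreement, net_by_model
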