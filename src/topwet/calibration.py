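"""Per-basin calibration of the transmissivity-decay parameter M.

M takes integer values 1..15.  For each basin the forward diagnostic is run
at every candidate M against the historical soil-moisture record, the RMSE
against the observed (mapped) wetland areas over the mapping periods is
computed, and the M with the minimum RMSE wins; ties go to the smallest M
(the weakest topographic control consistent with the data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    M_MAX,
    M_MIN,
    BasinRecord,
    SoilMoistureSeries,
    simulate_area_series,
)
from .errors import AlignmentError, MissingDataError

__all__ = ["MCalibration", "rmse", "calibrate_basin", "calibrate_all"]


@dataclass(frozen=True)
class MCalibration:
    """Winning M for one basin with the RMSE it achieved."""

    basin_id: str
    M: int
    rmse_km2: float
    n_periods_used: int


def rmse(sim: pd.Series, obs: pd.Series) -> float:
    """Root-mean-square error between two aligned area series (km^2)."""
    if len(sim) == 0 or len(obs) == 0:
        raise AlignmentError("rmse requires non-empty series")
    if len(sim) != len(obs) or set(sim.index) != set(obs.index):
        raise AlignmentError(
            f"windows misaligned: {list(sim.index)} vs {list(obs.index)}"
        )
    diff = sim - obs.reindex(sim.index)
    return float(np.sqrt(np.mean(np.square(diff.to_numpy()))))


def calibrate_basin(
    basin: BasinRecord,
    sm_hist: SoilMoistureSeries,
    obs: pd.Series,
    periods: Sequence[tuple[int, int]],
) -> MCalibration:
    """Grid-search M in {1..15} minimising RMSE against observed areas.

    ``obs`` is indexed by period label ("start-end"); NaN observations are
    dropped and the RMSE uses the remaining periods only (recorded in
    ``n_periods_used``).  All-NaN observations raise
    :class:`MissingDataError`.
    """
    obs = obs.dropna()
    if len(obs) == 0:
        raise MissingDataError(f"basin {basin.basin_id}: no usable observations")
    used = [p for p in periods if f"{p[0]}-{p[1]}" in set(obs.index)]
    if not used:
        raise MissingDataError(
            f"basin {basin.basin_id}: observations match no requested period"
        )
    obs = obs.loc[[f"{p[0]}-{p[1]}" for p in used]]

    errors = np.empty(M_MAX - M_MIN + 1)
    for k, m in enumerate(range(M_MIN, M_MAX + 1)):
        sim = simulate_area_series(basin, m, sm_hist, used)
        errors[k] = rmse(sim, obs)
    best = int(np.argmin(errors))  # argmin takes the first minimum: smallest M
    return MCalibration(
        basin_id=basin.basin_id,
        M=M_MIN + best,
        rmse_km2=float(errors[best]),
        n_periods_used=len(used),
    )


def calibrate_all(
    basins: Sequence[BasinRecord],
    sm_hist: Mapping[str, SoilMoistureSeries],
    obs_table: pd.DataFrame,
    periods: Sequence[tuple[int, int]],
) -> tuple[pd.DataFrame, list[str]]:
    """Calibrate every basin independently.

    ``obs_table`` needs columns basin_id, period, area_km2.  Basins missing
    from the table (or from ``sm_hist``) are collected in an exceptions list
    rather than aborting the run.  Returns (calibration table, exceptions).
    """
    by_basin = {bid: grp for bid, grp in obs_table.groupby("basin_id")}
    records, exceptions = [], []
    for basin in basins:
        grp = by_basin.get(basin.basin_id)
        if grp is None:
            exceptions.append(f"{basin.basin_id}: missing from observation table")
            continue
        if basin.basin_id not in sm_hist:
            exceptions.append(f"{basin.basin_id}: missing soil-moisture history")
            continue
        obs = pd.Series(
            grp["area_km2"].to_numpy(), index=grp["period"].to_numpy()
        )
        try:
            cal = calibrate_basin(basin, sm_hist[basin.basin_id], obs, periods)
        except MissingDataError as exc:
            exceptions.append(str(exc))
            continue
        records.append(cal)
    table = pd.DataFrame(
        [
            {
                "basin_id": c.basin_id,
                "M": c.M,
                "rmse_km2": c.rmse_km2,
                "n_periods_used": c.n_periods_used,
            }
            for c in records
        ]
    )
    return table, exceptions
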