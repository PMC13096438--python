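"""File formats: NetCDF soil-moisture/area cubes, basin CSVs, tidy tables.

NetCDF is written with xarray's scipy backend (NETCDF3_CLASSIC), which keeps
the files readable by any netCDF stack.  CSV tables carry a short
provenance header (stage and config hash) as ``#`` comment lines that
pandas skips on read.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .core import BasinRecord
from .errors import ValidationError

_SM_UNITS = {"kg m-2", "kg/m2", "kg/m^2", "kg m^-2"}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- NetCDF


def write_netcdf(da: xr.DataArray, path: str | Path) -> None:
    """Write a DataArray as a single-variable netCDF3 file."""
    name = da.name or "data"
    da.to_dataset(name=name).to_netcdf(path, engine="scipy")


def write_sm_cube(cube: xr.DataArray, path: str | Path) -> None:
    if "units" not in cube.attrs:
        cube = cube.copy()
        cube.attrs["units"] = "kg m-2"
    write_netcdf(cube.rename("soil_moisture"), path)


def read_sm_cube(path: str | Path) -> xr.DataArray:
    """Read and validate a soil-moisture cube.

    Accepts dims (model, scenario, time, basin) or any subset containing
    (time, basin); a missing model/scenario dimension is promoted to a
    singleton with a warning.  Units must declare kg/m^2; negative values
    are a hard error naming the offending index; NaNs are counted and
    flagged in ``attrs['n_missing']``.
    """
    ds = xr.open_dataset(path, engine="scipy")
    name = "soil_moisture" if "soil_moisture" in ds else list(ds.data_vars)[0]
    cube = ds[name].load()
    ds.close()
    for dim in ("time", "basin"):
        if dim not in cube.dims:
            raise ValidationError(f"cube is missing required dimension {dim!r}")
    for dim, default in (("scenario", "historical"), ("model", "model01")):
        if dim not in cube.dims:
            warnings.warn(
                f"cube has no {dim!r} dimension; promoting to single-{dim}",
                stacklevel=2,
            )
            cube = cube.expand_dims({dim: [default]})
    units = str(cube.attrs.get("units", ""))
    if units not in _SM_UNITS:
        raise ValidationError(
            f"soil-moisture units must be kg/m^2; file declares units={units!r}"
        )
    if "sm_sat" not in cube.attrs:
        raise ValidationError("cube is missing the sm_sat attribute")
    vals = cube.values
    neg = np.argwhere(vals < 0)
    if neg.size:
        idx = tuple(int(i) for i in neg[0])
        raise ValidationError(f"negative soil moisture at index {idx}")
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        warnings.warn(f"cube contains {n_missing} missing values", stacklevel=2)
    cube.attrs["n_missing"] = n_missing
    return cube.transpose("model", "scenario", "time", "basin")


# ---------------------------------------------------------------- basins


def write_basins(
    basins: Sequence[BasinRecord],
    basins_csv: str | Path,
    cti_csv: str | Path,
    header: str | None = None,
) -> None:
    """Basin attributes to one CSV, the CTI pixel samples to a long CSV."""
    attrs = pd.DataFrame(
        {
            "basin_id": [b.basin_id for b in basins],
            "area_km2": [b.area_km2 for b in basins],
            "cti_mean": [b.cti_mean for b in basins],
            "lat": [b.lat for b in basins],
            "lon": [b.lon for b in basins],
        }
    )
    write_table(attrs, basins_csv, header=header)
    pixels = pd.DataFrame(
        {
            "basin_id": np.repeat(
                [b.basin_id for b in basins], [b.n_pixels for b in basins]
            ),
            "cti": np.concatenate([b.cti_values for b in basins]),
        }
    )
    write_table(pixels, cti_csv, header=header)


def read_basins(basins_csv: str | Path, cti_csv: str | Path) -> list[BasinRecord]:
    attrs = read_table(basins_csv)
    pixels = read_table(cti_csv)
    grouped = {bid: grp["cti"].to_numpy() for bid, grp in pixels.groupby("basin_id")}
    basins = []
    for row in attrs.itertuples(index=False):
        if row.basin_id not in grouped:
            raise ValidationError(f"no CTI pixels for basin {row.basin_id}")
        basins.append(
            BasinRecord(
                basin_id=str(row.basin_id),
                area_km2=float(row.area_km2),
                cti_values=grouped[row.basin_id],
                lat=None if pd.isna(row.lat) else float(row.lat),
                lon=None if pd.isna(row.lon) else float(row.lon),
            )
        )
    return basins


# ---------------------------------------------------------------- tables


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    header: str | None = None,
    index: bool = False,
) -> None:
    """CSV with an optional ``#``-comment provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        # %.17g + round_trip parsing makes the CSV round trip bit-exact
        df.to_csv(fh, index=index, float_format="%.17g")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, comment="#", **kwargs)


def agreement_to_geojson(
    agreement: pd.DataFrame, cell_deg: float = 0.2
) -> dict:
    """Agreement table as a GeoJSON FeatureCollection of cell polygons."""
    from .projection import cell_south_west

    features = []
    for cell_id, row in agreement.iterrows():
        lat_s, lon_w = cell_south_west(str(cell_id), cell_deg)
        lat_n, lon_e = lat_s + cell_deg, lon_w + cell_deg
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [lon_w, lat_s],
                            [lon_e, lat_s],
                            [lon_e, lat_n],
                            [lon_w, lat_n],
                            [lon_w, lat_s],
                        ]
                    ],
                },
                "properties": {"cell_id": str(cell_id), **{k: float(v) for k, v in row.items()}},
            }
        )
    return {"type": "FeatureCollection", "features": features}
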