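"""End-to-end pipeline: generate -> calibrate -> project -> change stats.

Each stage can be skipped by pre-supplying its input file in the run
configuration; stages draw from independent seeded streams, so skipping one
does not shift another's random numbers.  Every output file gets a
provenance header (stage + config hash) and is checksummed into a JSON
manifest; a rerun with the same configuration and seed reproduces the
checksums byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .calibration import calibrate_all
from .change_stats import linear_trend, mann_kendall
from .config import RunConfig
from .errors import MissingDataError
from .projection import (
    agreement_map,
    assign_cells,
    continental_series,
    ensemble_mean,
    net_change_pct,
    project,
)
from .synthetic import (
    generate_basins,
    generate_observed_areas,
    generate_sm_cube,
    sm_series_from_cube,
)

log = logging.getLogger("topwet")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and return the artifact manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    chash = config.sha256()

    def hdr(stage: str) -> str:
        return f"topwet stage={stage} config_sha256={chash}"

    files: list[Path] = []
    manifest = {"config_sha256": chash, "files": {}}

    def register(path: Path) -> None:
        files.append(path)

    try:
        # ---- stage 1: basins -------------------------------------------
        true_m = None
        if config.inputs.basins_csv:
            log.info("stage basins: reading %s", config.inputs.basins_csv)
            basins = io.read_basins(config.inputs.basins_csv, config.inputs.cti_csv)
        else:
            log.info("stage basins: generating %d basins", config.generator.n_basins)
            basins, true_m = generate_basins(config.generator)
            io.write_basins(
                basins, out / "basins.csv", out / "cti_pixels.csv", header=hdr("basins")
            )
            io.write_table(
                true_m.rename_axis("basin_id").reset_index(),
                out / "true_m.csv",
                header=hdr("basins"),
            )
            register(out / "basins.csv")
            register(out / "cti_pixels.csv")
            register(out / "true_m.csv")

        # ---- stage 2: soil-moisture cube -------------------------------
        if config.inputs.sm_cube_nc:
            log.info("stage sm: reading %s", config.inputs.sm_cube_nc)
            cube = io.read_sm_cube(config.inputs.sm_cube_nc)
        else:
            log.info("stage sm: generating cube")
            cube = generate_sm_cube(basins, config.generator)
            io.write_sm_cube(cube, out / "sm_cube.nc")
            register(out / "sm_cube.nc")

        periods = config.calibration.resolved_periods()
        truth_model = str(cube["model"].values[0])
        truth_scenario = str(cube["scenario"].values[0])

        # ---- stage 3: observed areas -----------------------------------
        if config.inputs.observed_csv:
            obs_table = io.read_table(config.inputs.observed_csv)
        else:
            if true_m is None:
                raise MissingDataError(
                    "observed areas can only be generated for generated basins; "
                    "supply observed_csv alongside basins_csv"
                )
            log.info("stage observed: generating areas for %d periods", len(periods))
            obs_table = generate_observed_areas(
                basins, cube, periods, config.generator, true_m,
                truth_model=truth_model, truth_scenario=truth_scenario,
            )
            io.write_table(obs_table, out / "observed_areas.csv", header=hdr("observed"))
            register(out / "observed_areas.csv")

        # ---- stage 4: calibration --------------------------------------
        if config.inputs.calibration_csv:
            calib = io.read_table(config.inputs.calibration_csv)
        else:
            log.info("stage calibrate: grid search M over %d basins", len(basins))
            sm_hist = {
                b.basin_id: sm_series_from_cube(
                    cube, truth_model, truth_scenario, b.basin_id
                )
                for b in basins
            }
            calib, exceptions = calibrate_all(basins, sm_hist, obs_table, periods)
            io.write_table(calib, out / "calibration.csv", header=hdr("calibrate"))
            register(out / "calibration.csv")
            if exceptions:
                (out / "calibration_exceptions.txt").write_text(
                    "\n".join(exceptions) + "\n"
                )
                register(out / "calibration_exceptions.txt")

        # ---- stage 5: projection ---------------------------------------
        log.info("stage project: %d models x %d scenarios",
                 cube.sizes["model"], cube.sizes["scenario"])
        area_cube = project(basins, calib, cube, scenarios=config.projection.scenarios)
        io.write_netcdf(area_cube, out / "area_cube.nc")
        register(out / "area_cube.nc")

        cont = continental_series(area_cube)
        tidy = cont.to_dataframe(name="area_km2").reset_index()
        io.write_table(tidy, out / "continental_area.csv", header=hdr("project"))
        register(out / "continental_area.csv")

        mean = ensemble_mean(cont)
        mean_df = mean.to_dataframe(name="area_km2").reset_index()
        io.write_table(mean_df, out / "ensemble_mean_area.csv", header=hdr("project"))
        register(out / "ensemble_mean_area.csv")

        y0, y1 = config.projection.year0, config.projection.year1
        years = area_cube["year"].values
        y0 = int(max(y0, years.min()))
        y1 = int(min(y1, years.max()))
        changes = [
            {
                "scenario": str(s),
                "year0": y0,
                "year1": y1,
                "net_change_pct": round(
                    net_change_pct(mean.sel(scenario=s), y0, y1), 2
                ),
            }
            for s in area_cube["scenario"].values
        ]
        io.write_table(
            pd.DataFrame(changes), out / "net_change.csv", header=hdr("project")
        )
        register(out / "net_change.csv")

        # ---- stage 6: change stats -------------------------------------
        cells, unassigned = assign_cells(basins, config.projection.cell_deg)
        for s in area_cube["scenario"].values:
            agr, _ = agreement_map(
                area_cube.sel(scenario=str(s)),
                cells,
                y0,
                y1,
                epsilon_frac=config.projection.epsilon_frac,
            )
            path = out / f"agreement_{s}.csv"
            io.write_table(agr.reset_index(), path, header=hdr("change"))
            register(path)
            gj = io.agreement_to_geojson(agr, config.projection.cell_deg)
            gj_path = out / f"agreement_{s}.geojson"
            gj_path.write_text(json.dumps(gj))
            register(gj_path)
        if unassigned:
            (out / "cell_exceptions.txt").write_text("\n".join(unassigned) + "\n")
            register(out / "cell_exceptions.txt")

        trend_rows = []
        for s in area_cube["scenario"].values:
            series = mean.sel(scenario=str(s)).to_series()
            mk = mann_kendall(series.to_numpy())
            lf = linear_trend(series.to_numpy())
            trend_rows.append(
                {
                    "scenario": str(s),
                    "S": mk.S,
                    "Z": mk.Z,
                    "p_two_sided": mk.p_two_sided,
                    "slope_km2_per_yr": lf.slope,
                    "intercept_km2": lf.intercept,
                    "r_squared": lf.r_squared,
                }
            )
        io.write_table(pd.DataFrame(trend_rows), out / "trends.csv", header=hdr("trends"))
        register(out / "trends.csv")

        config.to_yaml(out / "config.yaml")
        register(out / "config.yaml")
    finally:
        # keep a (possibly partial) manifest whatever happened
        for path in files:
            if path.exists():
                manifest["files"][path.name] = io.sha256_file(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest
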