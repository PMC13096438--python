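"""Ensemble projection: area cubes, means, net change, agreement maps."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from topwet import (
    GeneratorConfig,
    agreement_map,
    assign_cells,
    continental_series,
    ensemble_mean,
    generate_basins,
    generate_sm_cube,
    net_change_pct,
    project,
    simulate_area_series,
    sm_series_from_cube,
)
from topwet.core import BasinRecord
from topwet.errors import MissingDataError, UndefinedPercentError
from topwet.projection import cell_south_west


def toy_cube(values, models, years, basins, scenario="SSP126"):
    """(model, scenario, year, basin) area cube from a plain array."""
    return xr.DataArray(
        np.asarray(values, float)[:, None, :, :],
        dims=("model", "scenario", "year", "basin"),
        coords={
            "model": models,
            "scenario": [scenario],
            "year": years,
            "basin": basins,
        },
        name="wetland_area",
    )


@pytest.fixture(scope="module")
def study(small_config_module=None):
    config = GeneratorConfig(
        n_basins=10, pixels_per_basin=300, n_models=3, year_range=(2015, 2040), seed=9
    )
    basins, _ = generate_basins(config)
    cube = generate_sm_cube(basins, config)
    calib = pd.DataFrame(
        {"basin_id": [b.basin_id for b in basins], "M": [5] * len(basins)}
    )
    return basins, cube, calib


class TestProject:
    def test_constant_sm_gives_flat_series(self):
        config = GeneratorConfig(
            n_basins=4,
            pixels_per_basin=200,
            n_models=2,
            year_range=(2015, 2030),
            sm_trend_frac_per_decade=0.0,
            sm_seasonal_amp_frac=0.0,
            sm_noise_sd_frac=0.0,
            seed=3,
        )
        basins, _ = generate_basins(config)
        cube = generate_sm_cube(basins, config)
        calib = {b.basin_id: 7 for b in basins}
        area = project(basins, calib, cube)
        cont = continental_series(area)
        assert (cont.std("year").values < 1e-9).all()
        for s in area["scenario"].values:
            assert net_change_pct(
                ensemble_mean(cont).sel(scenario=s), 2015, 2030
            ) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_basin_simulate_area_series(self, study):
        basins, cube, calib = study
        area = project(basins, calib, cube)
        for b in basins[:3]:
            for model in ("model01", "model03"):
                sm = sm_series_from_cube(cube, model, "SSP245", b.basin_id)
                expected = simulate_area_series(b, 5, sm, "annual")
                got = area.sel(model=model, scenario="SSP245", basin=b.basin_id)
                assert got.values == pytest.approx(expected.to_numpy())

    def test_positive_trend_gives_nondecreasing_series_without_noise(self):
        config = GeneratorConfig(
            n_basins=5,
            pixels_per_basin=300,
            n_models=3,
            year_range=(2015, 2060),
            sm_trend_frac_per_decade=0.05,
            sm_seasonal_amp_frac=0.0,
            sm_noise_sd_frac=0.0,
            model_trend_sd=0.0,
            seed=4,
        )
        basins, _ = generate_basins(config)
        cube = generate_sm_cube(basins, config)
        area = project(basins, {b.basin_id: 6 for b in basins}, cube)
        cont = continental_series(area)
        assert (cont.diff("year").values >= -1e-9).all()

    def test_uncalibrated_basin_rejected(self, study):
        basins, cube, calib = study
        with pytest.raises(MissingDataError):
            project(basins, calib.iloc[:-1], cube)

    def test_missing_scenario_skipped_with_warning(self, study):
        basins, cube, calib = study
        with pytest.warns(UserWarning, match="skipped"):
            area = project(basins, calib, cube, scenarios=["SSP126", "SSP999"])
        assert list(area["scenario"].values) == ["SSP126"]


class TestEnsembleSummaries:
    def test_mean_of_two_members_is_halfway(self):
        cube = toy_cube(
            [[[1.0, 3.0]], [[3.0, 5.0]]], ["m1", "m2"], [2020], ["b1", "b2"]
        )
        mean = ensemble_mean(cube)
        np.testing.assert_allclose(mean.values, [[[2.0, 4.0]]])

    def test_identical_members_collapse_to_any_member(self, study):
        basins, cube, calib = study
        area = project(basins, calib, cube)
        stacked = xr.concat([area.sel(model="model01")] * 3, dim="model")
        assert ensemble_mean(stacked).values == pytest.approx(
            area.sel(model="model01").values
        )

    def test_mean_matches_independent_recomputation(self, study):
        basins, cube, calib = study
        cont = continental_series(project(basins, calib, cube))
        mean = ensemble_mean(cont)
        by_hand = sum(
            cont.sel(model=m).values for m in cont["model"].values
        ) / cont.sizes["model"]
        assert mean.values == pytest.approx(by_hand)

    @pytest.mark.parametrize(
        "a0,a1,expected", [(100.0, 100.0, 0.0), (100.0, 110.0, 10.0)]
    )
    def test_net_change_pct(self, a0, a1, expected):
        s = pd.Series([a0, a1], index=[2023, 2100])
        assert net_change_pct(s, 2023, 2100) == pytest.approx(expected)

    def test_net_change_pct_matches_reported_precision_style(self):
        s = pd.Series([1_200_800.0, 1_200_800.0 - 6_100.0], index=[1984, 2021])
        assert round(net_change_pct(s, 1984, 2021), 2) == -0.51

    def test_zero_base_rejected(self):
        s = pd.Series([0.0, 10.0], index=[2023, 2100])
        with pytest.raises(UndefinedPercentError):
            net_change_pct(s, 2023, 2100)

    def test_scenario_ordering_propagates_to_end_of_century_area(self):
        config = GeneratorConfig(
            n_basins=15,
            pixels_per_basin=400,
            n_models=6,
            year_range=(2015, 2100),
            seed=21,
        )
        basins, _ = generate_basins(config)
        cube = generate_sm_cube(basins, config)
        area = project(basins, {b.basin_id: 5 for b in basins}, cube)
        end = ensemble_mean(continental_series(area)).sel(year=2100).values
        assert (np.diff(end) > 0).all()  # SSP126 < ... < SSP585


class TestCellsAndAgreement:
    def test_cell_assignment_round_trips_and_handles_missing_centroids(self):
        basins = [
            BasinRecord("a", 10.0, np.array([5.0]), lat=1.23, lon=30.41),
            BasinRecord("b", 10.0, np.array([5.0])),
        ]
        cells, exceptions = assign_cells(basins, 0.2)
        assert list(cells.index) == ["a"]
        assert exceptions == ["b: no centroid"]
        lat_s, lon_w = cell_south_west(cells["a"], 0.2)
        assert lat_s <= 1.23 < lat_s + 0.2
        assert lon_w <= 30.41 < lon_w + 0.2

    def test_unanimous_gain(self):
        cube = toy_cube(
            [[[10.0, 10.0], [20.0, 15.0]], [[10.0, 10.0], [30.0, 12.0]]],
            ["m1", "m2"],
            [2023, 2100],
            ["b1", "b2"],
        )
        cells = pd.Series({"b1": "r0c0", "b2": "r0c1"})
        agr, _ = agreement_map(cube, cells, 2023, 2100, epsilon_km2=0.5)
        assert (agr["n_gain"] == 2).all()
        assert (agr["n_loss"] == 0).all()

    def test_huge_epsilon_marks_everything_unchanged(self):
        cube = toy_cube(
            [[[10.0], [200.0]], [[10.0], [1.0]]], ["m1", "m2"], [2023, 2100], ["b1"]
        )
        cells = pd.Series({"b1": "r1c1"})
        agr, _ = agreement_map(cube, cells, 2023, 2100, epsilon_km2=1e9)
        assert (agr["n_unchanged"] == 2).all()

    def test_counts_match_brute_force_reclassification(self, rng):
        n_models, n_basins = 7, 20
        a = rng.uniform(0, 100, (n_models, 2, n_basins))
        cube = toy_cube(a, [f"m{i}" for i in range(n_models)], [2023, 2100],
                        [f"b{i}" for i in range(n_basins)])
        cells = pd.Series(
            {f"b{i}": f"r0c{i % 4}" for i in range(n_basins)}
        )
        eps = 5.0
        agr, net = agreement_map(cube, cells, 2023, 2100, epsilon_km2=eps)
        for cell in agr.index:
            members = [i for i in range(n_basins) if cells[f"b{i}"] == cell]
            loss = gain = unchanged = 0
            for m in range(n_models):
                d = sum(a[m, 1, i] - a[m, 0, i] for i in members)
                if d < -eps:
                    loss += 1
                elif d > eps:
                    gain += 1
                else:
                    unchanged += 1
            assert agr.loc[cell, "n_loss"] == loss
            assert agr.loc[cell, "n_gain"] == gain
            assert agr.loc[cell, "n_unchanged"] == unchanged

    def test_count_conservation_and_cellwise_net_totals(self, study):
        basins, cube, calib = study
        area = project(basins, calib, cube)
        cells, _ = assign_cells(basins)
        agr, net = agreement_map(area.sel(scenario="SSP370"), cells, 2015, 2040)
        n_models = area.sizes["model"]
        assert (
            agr["n_loss"] + agr["n_gain"] + agr["n_unchanged"] == n_models
        ).all()
        # sum of per-cell net changes reproduces the continental net change
        cont = continental_series(area.sel(scenario="SSP370"))
        for m in net.index:
            total = float(cont.sel(model=m, year=2040) - cont.sel(model=m, year=2015))
            assert net.loc[m].sum() == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_unassigned_basins_reported(self, study):
        basins, cube, calib = study
        area = project(basins, calib, cube)
        cells, _ = assign_cells(basins)
        cells = cells.drop(basins[0].basin_id)
        agr, _ = agreement_map(area.sel(scenario="SSP126"), cells, 2015, 2040)
        assert agr.attrs["unassigned_basins"] == [basins[0].basin_id]
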