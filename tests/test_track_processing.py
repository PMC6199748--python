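import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from fjordtrack.errors import ConfigurationError, InputError, InternalError
from fjordtrack.geospatial import CoastModel, GeoPoint, points_on_land
from fjordtrack.track_processing import (
    CorrectionConfig,
    InterpConfig,
    LCErrorTable,
    SdaConfig,
    correct_onland,
    interpolate_hourly,
    onland_percent,
    processing_report,
    rng_for_animal,
    sda_filter,
)

import oracles


def hourly_times(start, n):
    return pd.date_range(start, periods=n, freq="1h")


# ---------------------------------------------------------------------
# Config types
# ---------------------------------------------------------------------


class TestConfigs:
    def test_lc_error_table_defaults_monotone(self):
        t = LCErrorTable()
        assert t.radius("B") >= t.radius("A") >= t.radius("1") >= t.radius("2") >= t.radius("3")

    def test_lc_error_table_rejects_inversion(self):
        with pytest.raises(ConfigurationError):
            LCErrorTable({"3": 900.0, "2": 500.0, "1": 1500.0, "A": 2500.0, "B": 4000.0})

    def test_lc_error_table_rejects_missing_class(self):
        with pytest.raises(ConfigurationError, match="missing"):
            LCErrorTable({"3": 500.0, "2": 800.0})

    def test_z_uses_b_radius(self):
        assert LCErrorTable().radius("Z") == LCErrorTable().radius("B")

    def test_interp_config_step_vs_gap(self):
        with pytest.raises(ConfigurationError):
            InterpConfig(step=pd.Timedelta(hours=13), max_gap=pd.Timedelta(hours=12))

    def test_rng_for_animal_deterministic_and_distinct(self):
        a = rng_for_animal(1, "w1").random(3)
        b = rng_for_animal(1, "w1").random(3)
        c = rng_for_animal(1, "w2").random(3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


# ---------------------------------------------------------------------
# SDA filter
# ---------------------------------------------------------------------


class TestSdaFilter:
    def test_lc_z_always_removed(self, make_track):
        df = make_track(hourly_times("2014-08-01", 4), [16.0] * 4, [78.0] * 4, ["1", "Z", "A", "Z"])
        kept, removed = sda_filter(df)
        assert len(kept) == 2
        assert (removed["reason"] == "LC Z").all()
        assert len(removed) == 2

    def test_stationary_track_loses_only_z(self, make_track):
        lcs = ["3", "B", "Z", "A", "1", "Z", "2", "B"]
        df = make_track(hourly_times("2014-08-01", 8), [16.0] * 8, [78.0] * 8, lcs)
        kept, removed = sda_filter(df)
        assert set(removed["reason"]) == {"LC Z"}
        assert len(kept) == 6

    def test_displaced_fix_needing_5ms_removed(self, make_track, world_projection):
        # straight coastal track, 1.8 km/h eastward steps; fix 2 displaced
        # so that reaching it needs ~5 m/s from both neighbours
        proj = world_projection
        xs = np.array([0.0, 1800.0, 3600.0, 5400.0, 7200.0])
        ys = np.zeros(5)
        ys[2] += 5.0 * 3600.0  # 18 km perpendicular: 5 m/s both ways
        lons, lats = proj.inverse(xs, ys)
        df = make_track(hourly_times("2014-08-01", 5), lons, lats)
        kept, removed = sda_filter(df)
        assert len(removed) == 1
        assert removed["timestamp"].iloc[0] == df["timestamp"].iloc[2]
        assert removed["reason"].iloc[0] == "speed"
        assert len(kept) == 4

    def test_out_and_back_spike_apex_removed(self, make_track, world_projection):
        # spike embedded mid-track: 3 km legs at a 10 degree internal
        # angle -> rule (15deg, 2.5km); removing the apex is the unique
        # maximal repair (removing a neighbour leaves a spike)
        proj = world_projection
        import math

        xs = np.array([0.0, 1500.0, 2250.0, 3000.0, 4500.0, 6000.0])
        ys = np.array([0.0, 0.0, 8000.0, 0.0, 0.0, 0.0])  # apex 8 km north
        lons, lats = proj.inverse(xs, ys)
        df = make_track(hourly_times("2014-08-01", 6), lons, lats)
        kept, removed = sda_filter(df)
        assert len(removed) == 1
        assert removed["timestamp"].iloc[0] == df["timestamp"].iloc[2]
        assert removed["reason"].iloc[0].startswith("spike")

    def test_unsorted_input_rejected(self, make_track):
        df = make_track(
            ["2014-08-01 02:00", "2014-08-01 01:00", "2014-08-01 03:00"],
            [16.0, 16.01, 16.02],
            [78.0, 78.0, 78.0],
        )
        with pytest.raises(InputError):
            sda_filter(df)

    def test_all_z_track_gives_empty_result(self, make_track):
        df = make_track(hourly_times("2014-08-01", 3), [16.0] * 3, [78.0] * 3, ["Z", "Z", "Z"])
        kept, removed = sda_filter(df)
        assert len(kept) == 0
        assert len(removed) == 3

    def test_partition_and_order_preserved(self, rng):
        df = oracles.random_argos_track(rng, 8)
        kept, removed = sda_filter(df)
        assert len(kept) + len(removed) == len(df)
        assert kept["timestamp"].is_monotonic_increasing

    def test_idempotent(self, rng):
        for _ in range(20):
            df = oracles.random_argos_track(rng, 8)
            kept, _ = sda_filter(df)
            kept2, removed2 = sda_filter(kept)
            assert len(removed2) == 0
            pd.testing.assert_frame_equal(kept.reset_index(drop=True), kept2)

    def test_matches_brute_force_on_small_tracks(self, rng):
        # smoke-scale version of the acceptance criterion
        for _ in range(60):
            n = int(rng.integers(3, 9))
            df = oracles.random_nonborderline_track(rng, n)
            kept, _ = sda_filter(df)
            mine = sorted(df.index[df["timestamp"].isin(kept["timestamp"])].tolist())
            assert mine == oracles.brute_force_sda(df)


# ---------------------------------------------------------------------
# On-land correction
# ---------------------------------------------------------------------


class TestCorrectOnland:
    def test_at_sea_fix_passes_through(self, halfplane_model, world_projection, make_track):
        lon, lat = world_projection.inverse(-20_000.0, 0.0)
        df = make_track(hourly_times("2014-08-01", 1), [float(lon)], [float(lat)], ["A"])
        corr, removed = correct_onland(df, halfplane_model, CorrectionConfig(seed=1))
        assert len(removed) == 0
        assert corr["provenance"].iloc[0] == "original"
        assert corr["lon"].iloc[0] == df["lon"].iloc[0]

    def test_deep_inland_fix_removed(self, halfplane_model, world_projection, make_track):
        lon, lat = world_projection.inverse(200_000.0, 0.0)  # 200 km inland, radius ~ km
        df = make_track(hourly_times("2014-08-01", 1), [float(lon)], [float(lat)], ["3"])
        corr, removed = correct_onland(df, halfplane_model, CorrectionConfig(seed=1))
        assert len(corr) == 0
        assert len(removed) == 1

    def test_never_moves_more_than_radius(self, halfplane_model, world_projection, make_track, rng):
        proj = world_projection
        table = LCErrorTable()
        xs = rng.uniform(0.0, 2500.0, 20)  # on land, near the coast
        ys = rng.uniform(-50_000, 50_000, 20)
        lons, lats = proj.inverse(xs, ys)
        df = make_track(hourly_times("2014-08-01", 20), lons, lats, ["A"] * 20)
        corr, _ = correct_onland(df, halfplane_model, CorrectionConfig(seed=3, lc_errors=table))
        from fjordtrack.geospatial import geodesic_distance

        for _, row in corr[corr["provenance"] == "particle-corrected"].iterrows():
            orig = df[df["timestamp"] == row["timestamp"]].iloc[0]
            moved = geodesic_distance((orig["lon"], orig["lat"]), (row["lon"], row["lat"]))
            assert moved <= table.radius("A") * 1.001

    def test_corrected_positions_at_sea_with_timestamps_kept(
        self, halfplane_model, world_projection, make_track
    ):
        lon, lat = world_projection.inverse(500.0, 1000.0)
        df = make_track(hourly_times("2014-08-01", 1), [float(lon)], [float(lat)], ["B"])
        corr, _ = correct_onland(df, halfplane_model, CorrectionConfig(seed=2))
        assert corr["provenance"].iloc[0] == "particle-corrected"
        assert not points_on_land(corr["lon"].to_numpy(), corr["lat"].to_numpy(), halfplane_model)[0]
        assert corr["timestamp"].iloc[0] == df["timestamp"].iloc[0]
        assert corr["lc"].iloc[0] == "B"

    def test_bit_identical_under_fixed_seed(self, halfplane_model, world_projection, make_track):
        lon, lat = world_projection.inverse(500.0, -3000.0)
        df = make_track(hourly_times("2014-08-01", 3), [float(lon)] * 3, [float(lat)] * 3, ["A"] * 3)
        c1, _ = correct_onland(df, halfplane_model, CorrectionConfig(seed=9))
        c2, _ = correct_onland(df, halfplane_model, CorrectionConfig(seed=9))
        pd.testing.assert_frame_equal(c1, c2)

    def test_half_disc_displacement_small_n(self, halfplane_model, world_projection, make_track):
        # quick version of the analytic half-disc oracle
        R = 3000.0
        proj = world_projection
        lon, lat = proj.inverse(1.0, 0.0)  # effectively on the coastline
        df = make_track(hourly_times("2014-08-01", 1), [float(lon)], [float(lat)], ["A"])
        table = LCErrorTable({"3": R, "2": R, "1": R, "A": R, "B": R})
        cfg = CorrectionConfig(n_particles=5000, seed=4, lc_errors=table)
        corr, _ = correct_onland(df, halfplane_model, cfg)
        x, _y = proj.forward(corr["lon"].iloc[0], corr["lat"].iloc[0])
        expected = -4.0 * R / (3.0 * np.pi)
        se = 0.264 * R / np.sqrt(2500)  # sd of half-disc x-coordinate / sqrt(n at sea)
        assert abs(float(x) - expected) < 3 * se

    def test_missing_lc_in_table_raises(self, halfplane_model, world_projection, make_track):
        lon, lat = world_projection.inverse(500.0, 0.0)
        df = make_track(hourly_times("2014-08-01", 1), [float(lon)], [float(lat)], ["0"])
        with pytest.raises(ConfigurationError):
            correct_onland(df, halfplane_model, CorrectionConfig(seed=1))


# ---------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------


class TestInterpolateHourly:
    def test_two_fixes_4h_apart_give_5_collinear_points(
        self, halfplane_model, world_projection, make_track
    ):
        proj = world_projection
        (lon0, lat0) = (float(v) for v in proj.inverse(-20_000.0, 0.0))
        (lon1, lat1) = (float(v) for v in proj.inverse(-20_000.0, 8000.0))
        df = make_track(["2014-08-01 06:00", "2014-08-01 10:00"], [lon0, lon1], [lat0, lat1])
        out = interpolate_hourly(df, halfplane_model, projection=proj)
        assert len(out) == 5
        assert list(out["timestamp"]) == list(hourly_times("2014-08-01 06:00", 5))
        x, y = proj.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
        assert np.allclose(np.diff(x, 2), 0.0, atol=1e-6)
        assert np.allclose(np.diff(y, 2), 0.0, atol=1e-6)

    def test_gap_over_12h_not_interpolated(self, halfplane_model, world_projection, make_track):
        proj = world_projection
        (lon0, lat0) = (float(v) for v in proj.inverse(-20_000.0, 0.0))
        (lon1, lat1) = (float(v) for v in proj.inverse(-20_000.0, 5000.0))
        df = make_track(["2014-08-01 00:00", "2014-08-01 13:00"], [lon0, lon1], [lat0, lat1])
        out = interpolate_hourly(df, halfplane_model, projection=proj)
        assert len(out) == 0

    def test_offgrid_fix_times_absent(self, halfplane_model, world_projection, make_track):
        proj = world_projection
        (lon0, lat0) = (float(v) for v in proj.inverse(-20_000.0, 0.0))
        (lon1, lat1) = (float(v) for v in proj.inverse(-20_000.0, 5000.0))
        df = make_track(["2014-08-01 00:30", "2014-08-01 03:30"], [lon0, lon1], [lat0, lat1])
        out = interpolate_hourly(df, halfplane_model, projection=proj)
        assert list(out["timestamp"]) == list(hourly_times("2014-08-01 01:00", 3))

    def test_single_fix_gives_empty(self, halfplane_model, make_track):
        df = make_track(["2014-08-01 00:00"], [10.0], [77.0])
        out = interpolate_hourly(df, halfplane_model)
        assert len(out) == 0

    def test_headland_crossing_dropped_matches_replay(self, world_projection, make_track):
        # square headland jutting west; a straight N-S segment passes over it
        proj = world_projection
        km = 1000.0
        land_m = Polygon(
            [
                (0, -100 * km),
                (100 * km, -100 * km),
                (100 * km, 100 * km),
                (0, 100 * km),
                (0, 10 * km),
                (-20 * km, 10 * km),
                (-20 * km, -10 * km),
                (0, -10 * km),
            ]
        )
        model = CoastModel(
            "headland",
            land=[proj.project_inverse_geometry(land_m)],
            coastline=[proj.project_inverse_geometry(LineString(land_m.exterior.coords))],
        )
        (lon0, lat0) = (float(v) for v in proj.inverse(-10 * km, -40 * km))
        (lon1, lat1) = (float(v) for v in proj.inverse(-10 * km, 40 * km))
        df = make_track(["2014-08-01 00:00", "2014-08-01 08:00"], [lon0, lon1], [lat0, lat1])
        out = interpolate_hourly(df, model, projection=proj)
        # replay: same hourly grid, brute-force land test on linear interpolation
        expect = 0
        for k in range(9):
            frac = k / 8.0
            x = -10 * km
            y = -40 * km + frac * 80 * km
            lon, lat = proj.inverse(x, y)
            if not points_on_land(np.array([lon]), np.array([lat]), model)[0]:
                expect += 1
        assert 0 < len(out) < 9
        assert len(out) == expect


# ---------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------


class TestProcessingReport:
    def test_percentage_rule(self):
        assert onland_percent(25, 100) == 25
        assert onland_percent(3422, 15350) == 22
        assert onland_percent(6979, 28078) == 25

    def test_percentage_rejects_bad_counts(self):
        with pytest.raises(InputError):
            onland_percent(5, 0)
        with pytest.raises(InputError):
            onland_percent(10, 5)

    @pytest.fixture
    def stage_outputs(self, halfplane_model, world_projection, make_track):
        proj = world_projection
        # fix 2 sits just on land; legs around it stay under the 2.5 km
        # spike minimum so only the correction stage touches it
        xs = np.array([-4000.0, -3000.0, 500.0, -1800.0, -3500.0, -5000.0])
        lons, lats = proj.inverse(xs, np.zeros(6))
        lcs = ["1", "Z", "B", "A", "1", "2"]
        raw = make_track(hourly_times("2014-08-01", 6), lons, lats, lcs)
        kept, removed = sda_filter(raw)
        corrected, corr_removed = correct_onland(kept, halfplane_model, CorrectionConfig(seed=5))
        hourly = interpolate_hourly(corrected, halfplane_model, projection=proj)
        return raw, kept, removed, corrected, corr_removed, hourly

    def test_counts_reconcile_and_pool(self, stage_outputs):
        report = processing_report(*stage_outputs)
        pooled = report[report["animal_id"] == "all"].iloc[0]
        per_animal = report[report["animal_id"] != "all"]
        for col in ["n_raw", "n_sda_kept", "n_onland", "n_interpolated"]:
            assert per_animal[col].sum() == pooled[col]
        assert pooled["n_raw"] == 6
        assert pooled["n_sda_removed_lcz"] == 1
        assert pooled["n_onland"] == 1

    def test_inconsistent_stages_raise(self, stage_outputs):
        raw, kept, removed, corrected, corr_removed, hourly = stage_outputs
        with pytest.raises(InternalError):
            processing_report(raw, kept.iloc[:-1], removed, corrected, corr_removed, hourly)
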