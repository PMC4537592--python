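import math

import numpy as np
import pandas as pd
import pytest

from aeropath.simulate import (
    SimulationConfig,
    base_level_altitude,
    default_array,
    generate_dataset,
    make_birds,
    simulate_departures,
    simulate_path_table,
    simulate_probe_table,
    simulate_wind_field,
    wind_triangle_groundspeed,
)
from aeropath.wind import wind_components
from conftest import TEST_LEVELS


class TestDefaultArray:
    def test_five_stations(self, stations):
        assert len(stations) == 5

    def test_idh_antennas(self, idh_station):
        assert {a.boresight_deg for a in idh_station.antennas} == {55.0, 235.0}
        assert (idh_station.scan_on_s, idh_station.scan_period_s) == (14.0, 28.0)

    def test_petit_manan_antennas(self, stations):
        pm = next(s for s in stations if s.name == "PetitMananPt")
        assert {a.boresight_deg for a in pm.antennas} == {150.0, 330.0}

    def test_island_scan_cycle_and_range(self, stations):
        for s in stations:
            if s.name.startswith("KentIs"):
                assert (s.scan_on_s, s.scan_period_s) == (21.6, 43.2)
            assert s.detection_range_km == 15.0


class TestWindField:
    def test_zero_sds_give_constant_field(self):
        cfg = SimulationConfig(
            seed=3, levels=("10m", "925mb"), shared_evening_sd=0.0,
            level_evening_sd=0.0, node_noise_sd=0.0, n_evenings=5,
        )
        winds, _ = simulate_wind_field(cfg, np.random.default_rng(3))
        for lev, sub in winds.groupby("level_id"):
            assert sub["u"].nunique() == 1
            assert sub["v"].nunique() == 1

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=9, levels=TEST_LEVELS, n_evenings=6)
        w1, _ = simulate_wind_field(cfg, np.random.default_rng(9))
        w2, _ = simulate_wind_field(cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(w1, w2)

    def test_level_mean_tailwind_close_to_configured(self):
        # 925 mb configured at 6.5 m/s toward 260 deg; along a 249 deg track
        # the mean tailwind over many evenings approaches Vw cos(11 deg)
        cfg = SimulationConfig(seed=5, levels=("925mb",), n_evenings=100)
        _, evening = simulate_wind_field(cfg, np.random.default_rng(5))
        u, v = evening["vectors"][0, :, 0], evening["vectors"][0, :, 1]
        speed = np.hypot(u, v)
        direction = np.degrees(np.arctan2(u, v)) % 360
        tails = [wind_components(s, d, 249.0)[0] for s, d in zip(speed, direction)]
        expected = 6.5 * math.cos(math.radians(260 - 249))
        assert np.mean(tails) == pytest.approx(expected, abs=0.5)

    def test_geopotential_heights_near_climatology(self):
        cfg = SimulationConfig(seed=2, levels=("1000mb", "925mb"), n_evenings=40)
        _, evening = simulate_wind_field(cfg, np.random.default_rng(2))
        h1000 = evening["heights"][0]
        h925 = evening["heights"][1]
        assert np.mean(h1000) == pytest.approx(164.0, abs=30)
        assert np.mean(h925) == pytest.approx(816.5, abs=30)

    def test_base_altitude_labels(self):
        assert base_level_altitude("10m") == 10.0
        assert base_level_altitude("1000mb") == 164.0
        assert base_level_altitude("925mb") == pytest.approx(816.5)
        assert base_level_altitude("750mb") == pytest.approx(2339.0, abs=1)


class TestWindTriangle:
    def test_still_air(self):
        assert wind_triangle_groundspeed(12.0, 0.0, 0.0) == pytest.approx(12.0)

    def test_tailwind_additive(self):
        assert wind_triangle_groundspeed(12.0, 5.0, 0.0) == pytest.approx(17.0)

    def test_crosswind_penalty(self):
        assert wind_triangle_groundspeed(12.0, 0.0, 6.0) == pytest.approx(
            math.sqrt(144 - 36)
        )

    def test_excess_crosswind_aborts(self):
        with pytest.raises(ValueError):
            wind_triangle_groundspeed(12.0, 0.0, 12.5)

    def test_climb_reduces_horizontal_component(self):
        slow = wind_triangle_groundspeed(12.0, 0.0, 0.0, climb_rate_ms=2.0)
        assert slow == pytest.approx(math.sqrt(144 - 4))


class TestDepartures:
    def _birds(self, cfg, seed=0):
        return make_birds(cfg, np.random.default_rng(seed))

    def test_adults_depart_with_stronger_tailwinds(self):
        cfg = SimulationConfig(seed=1)
        rng = np.random.default_rng(1)
        tails = rng.normal(3.0, 2.5, cfg.n_evenings)
        out = simulate_departures(self._birds(cfg), tails, cfg, rng)
        dep = out.dropna(subset=["departure_evening"])
        mean_tail = dep.groupby("age")["departure_evening"].apply(
            lambda e: np.mean(tails[e.astype(int)])
        )
        assert mean_tail["adult"] > mean_tail["juvenile"]

    def test_all_supportive_everyone_departs_when_ready(self):
        cfg = SimulationConfig(seed=2)
        tails = np.full(cfg.n_evenings, 10.0)
        out = simulate_departures(self._birds(cfg), tails, cfg, np.random.default_rng(2))
        assert (out["departure_evening"] == out["ready_evening"]).all()

    def test_unattainable_adult_threshold(self):
        cfg = SimulationConfig(seed=3, adult_tailwind_threshold_ms=1e9)
        tails = np.full(cfg.n_evenings, 5.0)
        out = simulate_departures(self._birds(cfg), tails, cfg, np.random.default_rng(3))
        assert out.loc[out["age"] == "adult", "departure_evening"].isna().all()
        assert out.loc[out["age"] == "juvenile", "departure_evening"].notna().all()


class TestGenerateDataset:
    def test_default_seed_one_has_enough_two_stage_flights(self, small_dataset):
        two_stage = small_dataset.truth.groupby("tag_id")["stage"].nunique()
        assert (two_stage == 2).sum() >= 20

    def test_same_seed_byte_identical_csvs(self, tmp_path):
        cfg = SimulationConfig(seed=4, levels=("10m", "1000mb", "925mb"), n_adults=4,
                               n_juveniles=2, n_evenings=10)
        for name in ("a", "b"):
            generate_dataset(cfg).write(tmp_path / name)
        for fname in ("winds.csv", "detections.csv", "birds.csv", "truth.csv",
                      "stations.yaml"):
            assert (tmp_path / "a" / fname).read_bytes() == (
                tmp_path / "b" / fname
            ).read_bytes()

    def test_truth_groundspeed_consistency(self, small_dataset):
        t = small_dataset.truth
        gs = t["distance_km"] * 1000.0 / (t["duration_min"] * 60.0)
        np.testing.assert_allclose(gs, t["groundspeed_ms"], rtol=1e-9)

    def test_undetected_birds_have_no_petit_manan_rows(self, small_dataset):
        truth = small_dataset.truth
        coastal_tags = set(truth.loc[truth["stage"] == "coast", "tag_id"])
        det = small_dataset.detections
        pm_tags = set(det.loc[det["station"] == "PetitMananPt", "tag_id"])
        assert pm_tags == coastal_tags

    def test_ocean_slower_than_coast(self, small_dataset):
        t = small_dataset.truth
        med = t.groupby("stage")["groundspeed_ms"].median()
        assert med["coast"] > med["ocean"]

    def test_spurious_rate_zero_filter_is_noop(self, small_dataset):
        from aeropath.telemetry import filter_false_positives
        from aeropath.pipeline import _series_for

        det = small_dataset.detections
        tag = det["tag_id"].iloc[0]
        series = _series_for(det, tag, "InnerDoubleHeadshotIs")
        filtered = filter_false_positives(series, small_dataset.config.pulse_rate_s)
        assert filtered.times == series.times


class TestLightweightGenerators:
    def test_probe_table_shape_and_determinism(self):
        a = simulate_probe_table(3)
        b = simulate_probe_table(3)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["level_id"]) == set(
            ("10m", "30m", "1000mb", "975mb", "950mb", "925mb", "900mb")
        )
        per_level = a.groupby("level_id").size()
        assert (per_level == 24).all()

    def test_probe_table_duration_tracks_true_level_wind(self):
        tab = simulate_probe_table(5)
        true = tab[tab["level_id"] == "925mb"]
        r = np.corrcoef(true["tailwind_ms"], true["duration_min"])[0, 1]
        assert r < -0.5

    def test_path_table_shape(self):
        tab = simulate_path_table(1)
        assert len(tab) == 200
        assert set(tab["stage"]) == {0.0, 1.0}
        assert tab.groupby("individual_id").size().eq(2).all()

    def test_path_table_age_raises_tailwind(self):
        tab = simulate_path_table(2)
        means = tab.groupby("age")["tailwind"].mean()
        assert means[1.0] > means[0.0]
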