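"""The study generator: towers, wind, cohort, detections, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from motuskit import (SimulationConfig, build_tower_network, haversine_km,
                      simulate_cohort, simulate_detections, simulate_wind)
from motuskit.barrier_crossing import night_of


class TestTowerNetwork:
    def test_thirteen_origin_towers(self):
        towers = build_tower_network(SimulationConfig())
        counts = towers["region"].value_counts()
        assert counts["origin"] == 13
        assert counts["south_shore"] >= 2
        assert counts["corridor"] >= 2

    def test_south_shore_across_the_barrier(self):
        towers = build_tower_network(SimulationConfig())
        org = towers[towers["region"] == "origin"]
        for _, s in towers[towers["region"] == "south_shore"].iterrows():
            dmin = min(haversine_km(s["lat"], s["lon"], o["lat"], o["lon"])
                       for _, o in org.iterrows())
            assert dmin >= 50.0

    def test_corridor_spacing_100_to_400_km(self):
        towers = build_tower_network(SimulationConfig())
        cor = towers[towers["region"] == "corridor"].sort_values(
            "lat", ascending=False).reset_index(drop=True)
        for i in range(len(cor) - 1):
            d = haversine_km(cor.loc[i, "lat"], cor.loc[i, "lon"],
                             cor.loc[i + 1, "lat"], cor.loc[i + 1, "lon"])
            assert 100.0 <= d <= 400.0

    def test_deterministic_from_config(self):
        cfg = SimulationConfig(seed=9)
        pd.testing.assert_frame_equal(build_tower_network(cfg),
                                      build_tower_network(cfg))


class TestWind:
    def test_bounded_and_finite(self):
        g = simulate_wind(SimulationConfig(years=(2017,), seed=2))
        assert np.isfinite(g.u).all() and np.isfinite(g.v).all()
        assert np.abs(g.u).max() <= 40.0 and np.abs(g.v).max() <= 40.0

    def test_ar_zero_gives_uncorrelated_steps(self):
        cfg = SimulationConfig(years=(2017,), seed=4, wind_ar1=0.0)
        g = simulate_wind(cfg)
        x = g.u[:-1].ravel()[:1000]
        y = g.u[1:].ravel()[:1000]
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 0.1

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(years=(2017, 2018), seed=6)
        a, b = simulate_wind(cfg), simulate_wind(cfg)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)
        assert a.times.equals(b.times)


class TestCohort:
    def test_cohort_size_and_window(self):
        cfg = SimulationConfig(seed=5)
        dep, schedules = simulate_cohort(cfg)
        assert len(schedules) == 142  # 60 adults + 82 juveniles
        assert (dep["age_class"] == "adult").sum() == 60
        for s in schedules:
            w0 = pd.Timestamp(f"{s.year}-08-25", tz="UTC")
            w1 = pd.Timestamp(f"{s.year}-10-16", tz="UTC")
            assert w0 <= s.true_departure_ts <= w1 + pd.Timedelta(hours=12)
            assert s.true_minutes_after_sunset >= 0

    def test_unselective_birds_depart_on_drawn_date(self):
        base = SimulationConfig(n_adults=15, n_juveniles=15, years=(2017,),
                                seed=8)
        loose = dataclasses.replace(base,
                                    tailwind_selectivity_adult=-1e9,
                                    tailwind_selectivity_juvenile=-1e9)
        strict = dataclasses.replace(base,
                                     tailwind_selectivity_adult=1e9,
                                     tailwind_selectivity_juvenile=1e9)
        wind = simulate_wind(base)
        _, free = simulate_cohort(loose, wind=wind)
        _, capped = simulate_cohort(strict, wind=wind)
        # an infinitely selective bird waits the full cap; an unselective
        # one leaves immediately: same draws, shifted nights
        waits = [(c.true_departure_ts - f.true_departure_ts).days
                 for f, c in zip(free, capped)]
        assert all(w >= 0 for w in waits)
        assert max(waits) == base.max_wait_nights or any(
            c.true_departure_ts.month == 10 and c.true_departure_ts.day >= 15
            for c in capped)

    def test_age_gap_in_departure_dates_matches_parameters(self):
        """Monte-Carlo: the generator hits its own configured 9-day gap."""
        cfg0 = SimulationConfig(mean_departure_doy_adult=271,
                                mean_departure_doy_juvenile=262,
                                departure_doy_sd=7.0,
                                tailwind_selectivity_adult=-1e9,
                                tailwind_selectivity_juvenile=-1e9,
                                years=(2017,))
        wind = simulate_wind(cfg0)
        gaps_a, gaps_j = [], []
        for seed in range(10):
            cfg = dataclasses.replace(cfg0, seed=seed)
            _, schedules = simulate_cohort(cfg, wind=wind)
            for s in schedules:
                doy = s.true_departure_ts.dayofyear
                (gaps_a if s.age_class == "adult" else gaps_j).append(doy)
        gap = np.mean(gaps_a) - np.mean(gaps_j)
        assert gap == pytest.approx(9.0, abs=1.5)

    def test_zero_mass_window_rejected(self):
        cfg = SimulationConfig(mean_departure_doy_adult=100.0,
                               departure_doy_sd=0.5)
        with pytest.raises(ValueError, match="zero mass"):
            simulate_cohort(cfg)


class TestDetections:
    def _noise_free(self, **kw):
        return SimulationConfig(n_adults=8, n_juveniles=8, years=(2017,),
                                signal_noise_sd=0.0, missed_burst_prob=0.0,
                                false_run_rate=0.0, seed=12, **kw)

    def test_peak_burst_near_true_closest_approach(self):
        cfg = self._noise_free()
        towers = build_tower_network(cfg)
        wind = simulate_wind(cfg)
        _, schedules = simulate_cohort(cfg, wind=wind, towers=towers)
        det, truth = simulate_detections(schedules, towers, wind, cfg)
        for row in truth.passes.itertuples():
            sub = det[(det["tag_id"] == row.tag_id)
                      & (det["recv_id"] == row.recv_id)]
            near = sub[(sub["ts"] - row.true_peak_ts).abs()
                       < pd.Timedelta(minutes=10)]
            best = near.loc[near["sig"].idxmax(), "ts"]
            off = abs((best - row.true_peak_ts).total_seconds())
            assert off <= cfg.burst_interval_s

    def test_no_false_runs_means_all_tags_deployed(self):
        cfg = self._noise_free()
        towers = build_tower_network(cfg)
        wind = simulate_wind(cfg)
        dep, schedules = simulate_cohort(cfg, wind=wind, towers=towers)
        det, truth = simulate_detections(schedules, towers, wind, cfg)
        assert set(det["tag_id"]) <= set(dep["tag_id"])
        assert truth.false_detections.empty

    def test_bird_out_of_range_of_all_towers_is_silent(self):
        cfg = self._noise_free()
        towers = build_tower_network(cfg)
        towers = towers.assign(lon=towers["lon"] - 2.0)  # move network ~165 km away
        wind = simulate_wind(cfg)
        _, schedules = simulate_cohort(cfg, wind=wind, towers=towers)
        det, truth = simulate_detections(schedules, towers, wind, cfg)
        assert det.empty

    def test_trajectory_outside_wind_domain_names_bird(self):
        cfg = self._noise_free()
        towers = build_tower_network(cfg)
        wind = simulate_wind(cfg)
        _, schedules = simulate_cohort(cfg, wind=wind, towers=towers)
        schedules[3].deploy_lat = 10.0  # outside the grid
        with pytest.raises(ValueError, match=schedules[3].tag_id):
            simulate_detections(schedules, towers, wind, cfg)

    def test_determinism_byte_identical(self, tmp_path):
        from motuskit import simulate_study
        cfg = SimulationConfig(n_adults=5, n_juveniles=5, years=(2018,), seed=3)
        simulate_study(cfg, outdir=tmp_path / "a")
        simulate_study(cfg, outdir=tmp_path / "b")
        for name in ("detections.csv", "deployments.csv", "towers.csv",
                     "wind.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes(), name


def test_noise_free_peak_fit_recovers_all_passes(small_config):
    """Self-consistency: peak fitting recovers true passage sub-burst."""
    import dataclasses as dc
    from motuskit import assemble_runs, fit_signal_peak
    cfg = dc.replace(small_config, signal_noise_sd=0.0, missed_burst_prob=0.0,
                     false_run_rate=0.0)
    towers = build_tower_network(cfg)
    wind = simulate_wind(cfg)
    _, schedules = simulate_cohort(cfg, wind=wind, towers=towers)
    det, truth = simulate_detections(schedules, towers, wind, cfg)
    runs = assemble_runs(det, cfg.burst_interval_s)
    runs_ix = {}
    for r in runs:
        runs_ix.setdefault((r.tag_id, r.recv_id), []).append(r)
    checked = 0
    for row in truth.passes.itertuples():
        cands = [r for r in runs_ix.get((row.tag_id, row.recv_id), [])
                 if abs((r.mid_ts - row.true_peak_ts).total_seconds()) < 600]
        if not cands:
            continue
        run = cands[0]
        if run.length < 5:
            continue
        fit = fit_signal_peak(run)
        err = abs((fit.peak_ts - row.true_peak_ts).total_seconds())
        assert err < 0.5 * cfg.burst_interval_s
        checked += 1
    assert checked >= 30
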