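"""Signal-peak fitting, great-circle distance, and crossing records."""

import numpy as np
import pandas as pd
import pytest

from motuskit import (SimulationConfig, fit_signal_peak, haversine_km,
                      build_crossing, simulate_study)
from motuskit.departure_events import DepartureEvent
from motuskit.telemetry_io import WindGrid
from tests.conftest import make_run

# frozen WGS-84 geodesic references (geosphere::distGeo), km
GEODESIC_REFS = [
    ((42.6914, -80.4877), (41.8914, -80.4877), 88.8632),
    ((42.6914, -80.4877), (41.9500, -80.0000), 91.6429),
    ((42.7000, -80.5000), (39.0000, -82.0000), 429.8960),
    ((42.0000, -80.0000), (36.0000, -80.0000), 666.0942),
    ((44.0000, -75.0000), (34.0000, -85.0000), 1405.8607),
    ((42.5000, -80.3000), (41.2000, -81.1000), 158.9402),
]


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km(42.69, -80.49, 42.69, -80.49) == 0.0

    def test_meridian_arc_anchor(self):
        d = haversine_km(42.6914, -80.4877, 41.8914, -80.4877)
        assert d == pytest.approx(88.9, abs=0.2)

    @pytest.mark.parametrize("a,b,ref", GEODESIC_REFS)
    def test_within_03_percent_of_geodesic(self, a, b, ref):
        d = haversine_km(a[0], a[1], b[0], b[1])
        assert abs(d - ref) / ref <= 0.003

    def test_symmetry(self):
        d1 = haversine_km(42.0, -80.0, 39.5, -82.5)
        d2 = haversine_km(39.5, -82.5, 42.0, -80.0)
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestFitSignalPeak:
    def _parabola_run(self, vertex_s=600.0, curv=0.01, peak=30.0,
                      span=(400.0, 800.0), noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(span[0], span[1] + 1e-9, 12.7)
        sig = peak - curv * (t - vertex_s) ** 2 + rng.normal(0, noise, len(t))
        t0 = pd.Timestamp("2017-09-20T01:00:00Z")
        from motuskit.detection_filtering import Run
        df = pd.DataFrame({"tag_id": "A",
                           "ts": [t0 + pd.Timedelta(seconds=s) for s in t],
                           "recv_id": "R", "sig": sig})
        return Run(tag_id="A", recv_id="R", detections=df), t0

    def test_noiseless_vertex_recovered(self):
        run, t0 = self._parabola_run()
        fit = fit_signal_peak(run)
        got = (fit.peak_ts - t0).total_seconds()
        assert got == pytest.approx(600.0, abs=0.5)
        assert fit.clear and fit.curvature < 0 and fit.r2 > 0.999

    def test_monotone_signal_not_clear(self):
        run, _ = self._parabola_run(vertex_s=2000.0)  # vertex outside span
        fit = fit_signal_peak(run)
        assert not fit.clear

    def test_flat_signal_not_clear(self):
        run = make_run("A", "R", "2017-09-20T01:00:00Z", 8,
                       sigs=np.full(8, 20.0))
        fit = fit_signal_peak(run)
        assert not fit.clear

    def test_degenerate_timestamps_error(self):
        from motuskit.detection_filtering import Run
        t0 = pd.Timestamp("2017-09-20T01:00:00Z")
        df = pd.DataFrame({"tag_id": "A", "ts": [t0, t0, t0],
                           "recv_id": "R", "sig": [1.0, 2.0, 3.0]})
        run = Run(tag_id="A", recv_id="R", detections=df)
        with pytest.raises(ValueError, match="degenerate"):
            fit_signal_peak(run)

    def test_noisy_passes_median_error_under_15s(self):
        errs = []
        for seed in range(200):
            run, t0 = self._parabola_run(noise=3.0, seed=seed)
            fit = fit_signal_peak(run)
            errs.append(abs((fit.peak_ts - t0).total_seconds() - 600.0))
        assert np.median(errs) < 15.0

    def test_error_shrinks_with_noise(self):
        med = {}
        for sd in (3.0, 1.0, 0.1):
            errs = []
            for seed in range(60):
                run, t0 = self._parabola_run(noise=sd, seed=seed)
                fit = fit_signal_peak(run)
                errs.append(abs((fit.peak_ts - t0).total_seconds() - 600.0))
            med[sd] = np.median(errs)
        assert med[0.1] <= med[1.0] <= med[3.0]


class TestBuildCrossing:
    def _setup(self, towers_simple, north_sigs=None, south_sigs=None,
               south_start="2017-09-21T01:30:00Z"):
        def arc(n, peak=30.0):
            t = (np.arange(n) - n // 2) * 12.7
            return peak - 0.002 * t ** 2
        north = make_run("A", "N1", "2017-09-21T00:00:00Z", 17,
                         sigs=north_sigs if north_sigs is not None else arc(17))
        south = make_run("A", "S1", south_start, 17,
                         sigs=south_sigs if south_sigs is not None else arc(17))
        event = DepartureEvent(tag_id="A", year=2017,
                               departure_date=pd.Timestamp("2017-09-20").date(),
                               first_ts=north.start_ts, recv_id="N1",
                               minutes_after_sunset=45.0)
        times = pd.date_range("2017-09-20", periods=8, freq="6h", tz="UTC")
        wind = WindGrid(times=times, lats=np.array([40.0, 42.5, 45.0]),
                        lons=np.array([-82.5, -80.0]),
                        u=np.zeros((8, 3, 2)), v=np.full((8, 3, 2), -5.0))
        return event, [north, south], wind

    def test_speed_arithmetic(self, towers_simple):
        event, runs, wind = self._setup(towers_simple)
        rec, reason = build_crossing(event, runs, towers_simple, wind)
        assert reason is None
        # N1 (42.70) -> S1 (42.09): ~68 km; peaks 1.5 h apart
        assert rec.duration_h == pytest.approx(1.5, abs=0.01)
        assert rec.speed_kmh == pytest.approx(rec.distance_km / rec.duration_h)
        assert 40 < rec.speed_kmh < 50
        assert rec.tailwind_mps == pytest.approx(5.0)  # v=-5 southward flow

    def test_unclear_north_peak_gives_reason(self, towers_simple):
        event, runs, wind = self._setup(
            towers_simple, north_sigs=np.linspace(5, 30, 17))
        rec, reason = build_crossing(event, runs, towers_simple, wind)
        assert rec is None and reason == "no clear north peak"

    def test_unclear_south_peak_gives_reason(self, towers_simple):
        event, runs, wind = self._setup(
            towers_simple, south_sigs=np.linspace(5, 30, 17))
        rec, reason = build_crossing(event, runs, towers_simple, wind)
        assert rec is None and reason == "no clear south peak"

    def test_missing_south_run_gives_reason(self, towers_simple):
        event, runs, wind = self._setup(towers_simple)
        rec, reason = build_crossing(event, runs[:1], towers_simple, wind)
        assert rec is None and "south" in reason


def test_noise_free_crossing_speed_within_5pct():
    """Generator ground truth: estimated speed tracks true groundspeed."""
    cfg = SimulationConfig(n_adults=20, n_juveniles=20, years=(2017,),
                           signal_noise_sd=0.0, missed_burst_prob=0.0,
                           false_run_rate=0.0, seed=3)
    bundle = simulate_study(cfg)
    from motuskit.pipeline import run_pipeline_frames, PipelineConfig
    res = run_pipeline_frames(bundle["detections"], bundle["deployments"],
                              bundle["towers"], bundle["wind"],
                              PipelineConfig(burst_interval_s=cfg.burst_interval_s))
    truth = {s.tag_id: s.true_groundspeed_kmh for s in bundle["schedules"]}
    assert len(res.crossings) > 0
    for row in res.crossings.itertuples():
        rel = abs(row.speed_kmh - truth[row.tag_id]) / truth[row.tag_id]
        assert rel < 0.05, f"{row.tag_id}: {rel:.3f}"
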