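import numpy as np
import pandas as pd
import pytest

from motuskit import SimulationConfig, simulate_study


def make_run(tag, recv, start, n, interval_s=12.7, sigs=None):
    """Hand-built Run for constructed test cases."""
    from motuskit.detection_filtering import Run
    ts = pd.to_datetime(start, utc=True) + pd.to_timedelta(
        np.arange(n) * interval_s, unit="s")
    if sigs is None:
        sigs = np.full(n, 20.0)
    df = pd.DataFrame({"tag_id": tag, "ts": ts, "recv_id": recv,
                       "sig": np.asarray(sigs, dtype=float)})
    return Run(tag_id=tag, recv_id=recv, detections=df)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast structural tests."""
    return SimulationConfig(n_adults=10, n_juveniles=14, years=(2017, 2018),
                            seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale synthetic study at the default conditions."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def towers_simple():
    return pd.DataFrame({
        "recv_id": ["N1", "N2", "S1", "C1", "C2"],
        "lat": [42.70, 42.65, 42.09, 39.9, 37.3],
        "lon": [-80.50, -80.30, -80.45, -80.5, -80.5],
        "region": ["origin", "origin", "south_shore", "corridor", "corridor"],
    })
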