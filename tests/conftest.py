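import math

import numpy as np
import pytest
from hypothesis import settings

from tlsmeta import (
    ForestSceneConfig,
    PulseRecord,
    ReturnRecord,
    RoomSceneConfig,
    Scan,
    ScanPattern,
    generate_labeled_dataset,
)
from tlsmeta.metaproperties import extract_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# coarse grid (53 zenith x 40 azimuth = 2120 pulses) for fast sweeps; still
# includes the 90 deg row and the 0-30 / 30-35 bands
COARSE_PATTERN = ScanPattern(zenith_step=2.5, azimuth_step=9.0)


def make_pulse(pid, zenith, azimuth, returns=()):
    recs = tuple(ReturnRecord(i + 1, d, inten) for i, (d, inten) in enumerate(returns))
    return PulseRecord(pid, zenith, azimuth, recs)


def random_scan(rng, n_pulses=60, max_range=40.0):
    """Random small scan built through the object API (oracle-friendly)."""
    pulses = []
    for i in range(n_pulses):
        zen = rng.uniform(0, 180)
        az = rng.uniform(0, 360)
        k = rng.choice([0, 1, 1, 2])
        rets = []
        if k >= 1:
            d1 = rng.uniform(0.5, max_range * 0.7)
            rets.append((d1, rng.uniform(0, 1)))
        if k == 2:
            rets.append((rets[0][0] + rng.uniform(0.1, 5.0), rng.uniform(0, 1)))
        pulses.append(make_pulse(f"p{i}", zen, az, rets))
    return Scan(f"rand{rng.integers(1e6)}", pulses)


@pytest.fixture(scope="session")
def labeled_dataset():
    """Small rooms-vs-forests dataset shared across tests (10 + 14 scans)."""
    return generate_labeled_dataset(10, 14, pattern=COARSE_PATTERN, base_seed=42)


@pytest.fixture(scope="session")
def labeled_table(labeled_dataset):
    return extract_table(labeled_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
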