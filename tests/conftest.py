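import numpy as np
import pytest

from apneafusion.ingest import SegmentationConfig, WindowSet, segment_record
from apneafusion.synthetic import SimConfig, simulate_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_pair():
    """A 220 s paired recording with a handful of events."""
    cfg = SimConfig(duration_s=220.0, apnea_event_rate=50.0,
                    event_duration_s=(10.0, 20.0), seed=7)
    ecg, spo2 = simulate_pair(cfg)
    return cfg, ecg, spo2


@pytest.fixture(scope="session")
def windows_pair(sim_pair):
    _, ecg, spo2 = sim_pair
    seg = SegmentationConfig()
    return segment_record(ecg, seg), segment_record(spo2, seg)


def random_windowset(rng, n=30, width=64, fs=100.0, channel=None) -> WindowSet:
    return WindowSet(
        windows=rng.standard_normal((n, width)) + 1.0,
        labels=rng.integers(0, 2, n),
        fs=fs,
        source_ids=["r0"] * n,
        start_times_s=np.arange(n, dtype=float),
        channel=channel,
    )
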