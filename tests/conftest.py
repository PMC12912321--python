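import numpy as np
import pytest

from mcma.synthetic_data import SynthConfig, simulate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free, jitter-free 12-s recording at 60 bpm."""
    cfg = SynthConfig(hr_bpm=60.0, duration=12.0, hr_jitter=0.0,
                      noise_sd=0.0, seed=7)
    return simulate_record(cfg, record_id="clean60")


@pytest.fixture(scope="session")
def clean_window(clean_record):
    """The first 1024-sample window of the clean recording."""
    from mcma.io_windowing import window_record

    return window_record(clean_record.record)[0]
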