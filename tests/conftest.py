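import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 100.0


@pytest.fixture(scope="session")
def time_10s():
    return np.arange(1000) / FS


def make_sine(freq, amp=1.0, n=1000, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def clean_epoch():
    """Noiseless single-harmonic epoch: pure 2 Hz on VT/AP, 1 Hz on ML."""
    import gaitrisk as gr

    params = gr.GaitSignalParams(
        stride_frequency=1.0,
        harmonic_amplitudes_even={"vt": (1.0, 0, 0, 0), "ml": (0, 0, 0, 0),
                                  "ap": (1.0, 0, 0, 0)},
        harmonic_amplitudes_odd={"vt": (0, 0, 0, 0), "ml": (0.5, 0, 0, 0),
                                 "ap": (0, 0, 0, 0)},
        asymmetry=0.0,
        noise_sd=0.0,
        freq_jitter_sd=0.0,
    )
    return gr.synth_gait_epoch(params, seed=0)


@pytest.fixture(scope="session")
def default_epoch():
    import gaitrisk as gr

    return gr.synth_gait_epoch(gr.GaitSignalParams(), seed=1)
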