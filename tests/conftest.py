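import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermogate as tg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_video(rng):
    """Small random 8x8 video for oracle comparisons."""
    frames = 25.0 + rng.normal(0, 1.0, size=(40, 8, 8))
    return tg.ThermalVideo(frames, fps=10.0)


@pytest.fixture
def clean_scene_video():
    """Noise-free masked-subject render of a 60 s, 20 bpm protocol."""
    scene = tg.SceneConfig(noise_sd=0.0, quant_step=0.0)
    protocol = tg.ProtocolConfig(((60.0, 20.0),))
    return tg.render_video(scene, protocol)


def sinusoid_signal(freq_hz, duration_s=60.0, fps=10.0, amp=1.0, phase=0.0, offset=0.0):
    t = np.arange(int(round(duration_s * fps))) / fps
    return tg.RespiratorySignal(offset + amp * np.sin(2 * np.pi * freq_hz * t + phase), fps)
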