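import numpy as np
import pytest

from mapgap.config import DetectorConfig, SimulationConfig
from mapgap.detection import BeatWindow


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Respiration-free configuration for tests that need exact elicitation."""
    return SimulationConfig(seed=42, breath_hold=True)


@pytest.fixture
def detector() -> DetectorConfig:
    return DetectorConfig()


def make_window(
    sig: np.ndarray,
    fs: float = 1000.0,
    start_time: float = 0.0,
    force: np.ndarray | None = None,
) -> BeatWindow:
    """Wrap a raw signal as a single beat window for direct assessment."""
    return BeatWindow(
        beat_index=0,
        qrs_time=start_time,
        start_time=start_time,
        sample_rate=fs,
        map_mv=np.asarray(sig, dtype=float),
        force_g=force,
    )


def synthetic_map_window(
    amplitude: float,
    duration_ms: float,
    fs: float = 1000.0,
    pre_ms: float = 100.0,
    total_ms: float = 700.0,
) -> tuple[BeatWindow, float]:
    """A clean MAP-shaped window built independently of the generator:
    flat zero baseline, instantaneous upstroke, plateau, linear decay that
    crosses 90% recovery exactly ``duration_ms`` after the upstroke.

    Returns (window, earliest_activation_time); activation lands exactly at
    ``pre_ms`` + 1 sample and the measured MAPDUR equals ``duration_ms``.
    """
    n = int(total_ms * fs / 1000)
    sig = np.zeros(n)
    a = int(pre_ms * fs / 1000) + 1  # activation sample (max upstroke)
    dur = int(duration_ms * fs / 1000)
    plateau_end = a + dur // 2
    eor = a + dur  # sample where the signal hits the 90% recovery level
    level = 0.1 * amplitude
    sig[a:plateau_end] = amplitude
    ndec = eor - plateau_end + 1
    sig[plateau_end : eor + 1] = np.linspace(amplitude, level, ndec)
    sig[eor + 1 :] = 0.0
    eat = (a - 60) / fs  # earliest ventricular activation 60 samples earlier
    return make_window(sig, fs=fs), eat
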