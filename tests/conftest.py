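import numpy as np
import pytest

from hrvgap import BeatSeries, SynthParams, synth_beats


@pytest.fixture(scope="session")
def quiet_window():
    """300-s tone-only window (no noise): clean LF/HF spectral ground truth."""
    return synth_beats(SynthParams(300.0, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_window():
    """300-s window with default beat-scale noise: all features nonzero."""
    return synth_beats(SynthParams(300.0, seed=5))


@pytest.fixture
def constant_rr():
    """125 beats at exactly 0.8 s spacing."""
    return BeatSeries(0.8 * np.arange(1, 126))
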