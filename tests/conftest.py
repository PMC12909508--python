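import numpy as np
import pytest

from epilobe import synth


@pytest.fixture(scope="session")
def frontal_recording():
    """30-s synthetic recording with one High-tier frontal seizure."""
    cfg = synth.SynthConfig(
        duration=30.0,
        seed=3,
        seizure_events=[synth.SeizureEvent(10.0, 20.0, "frontal", "High")],
    )
    return synth.generate_recording(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
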