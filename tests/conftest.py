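import numpy as np
import pytest

import scalphfo as sh


@pytest.fixture(scope="session")
def lna_recording():
    """5-min 4-channel low-noise recording with injected ripples (+ truth)."""
    spec = sh.RecordingSpec(
        duration_s=300.0, fs_hz=2000.0,
        channel_labels=["C4", "P4", "C3", "P3"], seed=11,
    )
    return sh.make_recording(spec)


@pytest.fixture(scope="session")
def lna_events(lna_recording):
    rec, _ = lna_recording
    return sh.detect(rec, band="ripple")


@pytest.fixture(scope="session")
def table1():
    return sh.table1_summaries()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
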