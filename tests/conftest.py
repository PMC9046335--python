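import numpy as np
import pandas as pd
import pytest

from gazephys.containers import GazeRecording
from gazephys.simulate import DEFAULT_SCREEN, SimConfig


@pytest.fixture(scope="session")
def geometry():
    """The validation study's display geometry (53×30 cm, 1920×1080, 62.45 cm)."""
    return DEFAULT_SCREEN


@pytest.fixture
def stationary_recording(geometry):
    """A clean 150 Hz recording fixating a single point."""
    n = 300
    t = np.arange(n) / 150.0
    samples = pd.DataFrame(
        {
            "t": t,
            "x_px": np.full(n, 960.0),
            "y_px": np.full(n, 540.0),
            "valid": np.ones(n, bool),
            "pupil_mm": np.full(n, 4.0),
        }
    )
    return GazeRecording(samples, geometry, nominal_rate_hz=150.0)


def make_recording(t, x, y, valid=None, geometry=DEFAULT_SCREEN, rate=150.0, pupil=None):
    n = len(t)
    return GazeRecording(
        pd.DataFrame(
            {
                "t": np.asarray(t, float),
                "x_px": np.asarray(x, float),
                "y_px": np.asarray(y, float),
                "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
                "pupil_mm": np.full(n, np.nan) if pupil is None else np.asarray(pupil, float),
            }
        ),
        geometry,
        nominal_rate_hz=rate,
    )


@pytest.fixture
def default_config():
    return SimConfig(seed=1234)
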