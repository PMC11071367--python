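import numpy as np
import pandas as pd
import pytest

from phenomap.sleepsig import EpochGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(stages, emg_rms=None, rbd=None, delta=None, theta=None,
              artifact=None, epoch_s=20.0):
    """Minimal epoch grid for staging/RBD tests."""
    stages = np.asarray(stages)
    n = len(stages)
    frame = pd.DataFrame({
        "time_s": epoch_s * np.arange(n),
        "emg_rms": emg_rms if emg_rms is not None else np.full(n, 0.1),
        "delta": delta if delta is not None else np.full(n, 30.0),
        "theta": theta if theta is not None else np.full(n, 20.0),
        "alpha": 5.0, "sigma": 5.0, "beta": 5.0,
        "low_gamma": 5.0, "high_gamma": 5.0,
        "stage": stages,
        "artifact": artifact if artifact is not None else np.zeros(n, bool),
        "rbd": rbd if rbd is not None else np.zeros(n, bool),
    })
    return EpochGrid(frame, epoch_s, 500.0)
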