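import numpy as np
import pytest

import granulemotion as gm


@pytest.fixture()
def acq100() -> gm.AcquisitionConfig:
    """100-frame acquisition at the standard 204 ms frame interval."""
    return gm.AcquisitionConfig(n_frames=100)


@pytest.fixture()
def brownian() -> gm.MotionModel:
    return gm.MotionModel(kind="brownian", D=5e-3, sigma_loc=0.02)


@pytest.fixture()
def immobile_noisy() -> gm.MotionModel:
    return gm.MotionModel(kind="immobile", sigma_loc=0.02)


@pytest.fixture()
def drifted() -> gm.MotionModel:
    return gm.MotionModel(kind="drifted", v=0.5, D=1e-3, heading=0.7, sigma_loc=0.02)


def random_gapped_track(rng: np.random.Generator, n: int = 30, dt: float = 0.204) -> gm.Trajectory:
    """A random-walk track with random interior frame gaps, for oracles."""
    frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
    return gm.Trajectory(
        track_id=0,
        frames=frames,
        x=np.cumsum(rng.normal(0, 0.05, n)),
        y=np.cumsum(rng.normal(0, 0.05, n)),
        dt=dt,
    )
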