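import numpy as np
import pytest

import hcasim as h


@pytest.fixture(scope="session")
def short_cfg() -> h.SimConfig:
    """Half-hour default cage used by several unit tests."""
    return h.SimConfig(duration_s=1800.0, seed=7)


@pytest.fixture(scope="session")
def short_truth(short_cfg) -> h.CohortTruth:
    return h.simulate_cohort(short_cfg)


@pytest.fixture(scope="session")
def short_reads(short_truth):
    return h.simulate_readstream(short_truth, h.AntennaArray(), h.CouplingModel(), seed=21)


def stationary_truth(x_cm: float, y_cm: float, height_cm: float, axis,
                     duration_s: float, timestep_s: float = 0.1,
                     n_animals: int = 1) -> h.CohortTruth:
    """Hand-built ground truth: motionless animals at one spot."""
    cfg = h.SimConfig(duration_s=duration_s, timestep_s=timestep_s,
                      n_animals=n_animals, seed=0)
    n = int(round(duration_s / timestep_s))
    t = np.arange(n) * timestep_s
    shape = (n_animals, n)
    ones = np.ones(shape, np.float32)
    ax = np.zeros(shape + (3,), np.float32)
    ax[:, :, 0], ax[:, :, 1], ax[:, :, 2] = axis
    return h.CohortTruth(
        cfg=cfg, t=t,
        x=ones * x_cm, y=ones * y_cm,
        tag_x=ones * x_cm, tag_y=ones * y_cm,
        tag_height=ones * height_cm, axis=ax,
        temp=ones * 37.5,
        posture=np.zeros(shape, np.int8),
        step=np.zeros(shape, bool),
    )
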