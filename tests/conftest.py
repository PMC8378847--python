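import numpy as np
import pytest

from physiofc import cohort_sim as cs


@pytest.fixture(scope="session")
def mini_config() -> cs.SimConfig:
    return cs.SimConfig(
        n_subjects=3,
        n_sessions=2,
        n_frames=300,
        n_rois=18,
        physio_fs=60,
        n_wm_voxels=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    """3 subjects x 2 days x {LR, RL}: 12 simulated scans with ground truth."""
    return list(cs.iter_cohort(mini_config))


@pytest.fixture(scope="session")
def one_scan(mini_cohort):
    return mini_cohort[0][1]


@pytest.fixture(scope="session")
def default_snr_cohort():
    """20 scans at the generator's default scan geometry and gain scales."""
    config = cs.SimConfig(n_subjects=5, n_rois=40, seed=21)
    return list(cs.iter_cohort(config))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
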