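import numpy as np
import pytest

from cinesync import BoldRun, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(data_tv: np.ndarray, tr_s: float = 2.47, grid=None, subject_id="sub-test"):
    """Wrap a (T, V) matrix as a BoldRun on a synthetic grid."""
    t, v = data_tv.shape
    if grid is None:
        grid = (v, 1, 1)
    assert np.prod(grid) == v
    return BoldRun(
        data=data_tv.T.reshape(*grid, t),
        tr_s=tr_s,
        subject_id=subject_id,
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Small nuisance-free cohort: 12 subjects, 2 networks, low noise."""
    cfg = SimulationConfig(
        n_subjects=12,
        n_timepoints=120,
        grid_shape=(8, 8, 6),
        n_networks=2,
        noise_sd=0.3,
        drift_amplitude=0.0,
        spike_rate_per_frame=0.0,
        seed=42,
    )
    runs, truth, table = simulate_cohort(cfg)
    return cfg, runs, truth, table
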