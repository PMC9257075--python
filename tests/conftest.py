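import numpy as np
import pytest

from trajalign import CohortConfig, Trajectory, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_trajectory():
    """3-sample, 3-feature trajectory with distinct compositions."""
    return Trajectory(
        "T1",
        [10.0, 40.0, 95.0],
        np.array([[0.7, 0.2, 0.1], [0.3, 0.4, 0.3], [0.1, 0.2, 0.7]]),
        ["fA", "fB", "fC"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject default-style cohort shared across read-only tests."""
    trajs, meta, truth = generate_cohort(CohortConfig(n_subjects=12, seed=99))
    return trajs, meta, truth


def make_trajectory(times, samples, subject="S", features=None):
    samples = np.asarray(samples, dtype=float)
    if features is None:
        features = [f"f{i}" for i in range(samples.shape[1])]
    return Trajectory(subject, times, samples, features)
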