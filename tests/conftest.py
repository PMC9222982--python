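import numpy as np
import pytest

from roicox import GeneratorConfig, PairedSurvivalTask, SurvivalTask, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    """Six patients, two features, mixed censoring, one tied event time."""
    return SurvivalTask(
        sample_ids=["a", "b", "c", "d", "e", "f"],
        X=np.array(
            [[0.5, -1.0], [1.2, 0.3], [-0.7, 0.9], [0.0, 0.0], [2.0, -0.5], [-1.5, 1.1]]
        ),
        t=np.array([5.0, 3.0, 3.0, 8.0, 1.0, 6.0]),
        e=np.array([1, 1, 0, 0, 1, 1]),
        name="toy",
    )


@pytest.fixture
def small_paired(small_task):
    return PairedSurvivalTask(
        base=small_task,
        t_aux=np.array([4.0, 2.0, 5.0, 7.0, 1.5, 6.0]),
        e_aux=np.array([1, 1, 1, 0, 1, 0]),
    )


@pytest.fixture(scope="session")
def mid_paired():
    """A moderate synthetic cohort for fitter tests (fast but non-trivial)."""
    paired, truth = generate(
        GeneratorConfig(n_patients=80, n_features=8, n_events_target=55, seed=20)
    )
    return paired, truth
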