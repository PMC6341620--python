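import numpy as np
import pytest

from medlogit import (
    BINARY,
    CONTINUOUS,
    Condition,
    MediationDataset,
    StudyConfig,
    generate_dataset,
    run_study,
    true_effects,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190121)


def simulate_dataset(mediator_type: str, n: int, seed: int) -> MediationDataset:
    """One dataset from the default generating model (all paths 0.6)."""
    cond = (
        Condition(CONTINUOUS, y_prevalence=0.5, n=n)
        if mediator_type == CONTINUOUS
        else Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5, n=n)
    )
    return generate_dataset(cond, true_effects(cond), seed)


@pytest.fixture(scope="session")
def continuous_dataset():
    return simulate_dataset(CONTINUOUS, n=1000, seed=7)


@pytest.fixture(scope="session")
def binary_dataset():
    return simulate_dataset(BINARY, n=1000, seed=7)


@pytest.fixture(scope="session")
def fullscale_study():
    """Full-scale study (500 reps x n=1000) for the two headline conditions.

    Session-scoped because several tests read different rows of the same
    performance table; ~6 s to compute.
    """
    conditions = (
        Condition(CONTINUOUS, y_prevalence=0.5),
        Condition(BINARY, y_prevalence=0.5, m_prevalence=0.5),
    )
    return run_study(StudyConfig(conditions=conditions, base_seed=20190121))
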