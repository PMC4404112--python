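import numpy as np
import pytest

from traumadfr import (
    ExpressionMatrix, SampleMeta, SimulationParams, build_reference,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20150304)


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples with hand-enterable values."""
    values = np.array([
        [1.0, 3.0, 2.0, 4.0],
        [5.0, 5.0, 6.0, 6.0],
        [0.5, 1.5, 2.5, 3.5],
    ])
    return ExpressionMatrix(("pA", "pB", "pC"), ("s1", "s2", "s3", "s4"), values)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure synthetic cohort at reduced size, with truth."""
    params = SimulationParams(n_probes=300, n_controls=12,
                              n_patients_per_cell=10, dropout_hazard=0.0,
                              seed=42)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def small_reference(small_cohort):
    matrix, metadata, _ = small_cohort
    controls = [m.sample_id for m in metadata if m.age_group == "control"]
    return build_reference(matrix, controls)


def control_ids(metadata):
    return [m.sample_id for m in metadata if m.age_group == "control"]
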