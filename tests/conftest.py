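import numpy as np
import pytest

import frailkit as fk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_class_cohort():
    """Moderately separated synthetic cohort shared across modules."""
    config = fk.SimConfig(n_subjects=400, seed=42, missing_rate=0.02)
    cohort, truth = fk.simulate_cohort(config)
    return cohort, truth, config


@pytest.fixture(scope="session")
def separated_scores():
    """Two well-separated Gaussian blobs in 3-D with labels."""
    gen = np.random.default_rng(7)
    a = gen.normal(size=(60, 3))
    b = gen.normal(size=(60, 3)) + 6.0
    scores = np.vstack([a, b])
    labels = np.array([0] * 60 + [1] * 60)
    return scores, labels
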