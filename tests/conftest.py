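import numpy as np
import pytest

import geotwin as gt


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 mixed-zygosity pairs with one incomplete pair."""
    pairs = gt.simulate_cohort(
        gt.homogeneous_field(0.6, 0.1, 0.3),
        gt.CohortConfig(n_pairs=20, seed=42, incomplete_pair_fraction=0.1),
    )
    assert any(p.y1 is None or p.y2 is None for p in pairs)
    return pairs


@pytest.fixture(scope="session")
def homogeneous_cohort_5000():
    """n=5000 standardized cohort generated at (a2=0.65, c2=0, e2=0.35)."""
    pairs = gt.simulate_cohort(
        gt.homogeneous_field(0.65, 0.0, 0.35),
        gt.CohortConfig(n_pairs=5000, seed=1, sex_variance_share=0.0,
                        incomplete_pair_fraction=0.0),
    )
    return gt.standardize_phenotype(pairs)


@pytest.fixture(scope="session")
def step_cohort_4000():
    """Structured (step-field) standardized cohort for smoothing tests."""
    field = gt.make_step_field(0.5, (0.55, 0.0, 0.45), (0.91, 0.0, 0.09))
    pairs = gt.simulate_cohort(field, gt.CohortConfig(n_pairs=4000, seed=5))
    return gt.standardize_phenotype(pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
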