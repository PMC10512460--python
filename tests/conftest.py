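import numpy as np
import pytest

from cpmsvm import CohortDataset, EffectPlan, generate_cohort
from cpmsvm.simulate import sample_effect_plan


@pytest.fixture(scope="session")
def small_random_cohort() -> CohortDataset:
    """20 subjects x 45 edges (10 nodes) of pure noise; no group effect."""
    plan = EffectPlan(n_nodes=10, delta=0.0)
    return generate_cohort(plan, 10, 10, seed=101)


@pytest.fixture(scope="session")
def planted_cohort() -> CohortDataset:
    """Strong bidirectional effects: 8 up + 8 down at 3 sigma, 15 nodes, n=40."""
    plan = sample_effect_plan(15, 8, 8, seed=7, delta=0.6, noise_sd=0.2)
    return generate_cohort(plan, 20, 20, seed=8)


@pytest.fixture(scope="session")
def planted_plan() -> EffectPlan:
    return sample_effect_plan(15, 8, 8, seed=7, delta=0.6, noise_sd=0.2)
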