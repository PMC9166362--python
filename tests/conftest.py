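import numpy as np
import pytest

from septime import GrowthLaw, RecruitmentModel, simulate_population


def constant_expression(level: float = 1000.0):
    """Expression law with age-independent expected total fluorescence."""
    return lambda ages: np.full_like(np.asarray(ages, dtype=float), level)


@pytest.fixture
def growth_law():
    return GrowthLaw(birth_length=2.0, diameter=1.0)


@pytest.fixture
def noiseless_population(growth_law):
    """Small noiseless simulated replicate with onset at age 0.25."""
    model = RecruitmentModel(t0_true=0.25, rise_width=0.2, plateau_fraction=0.6)
    return simulate_population(300, growth_law, model, seed=7)


@pytest.fixture
def noisy_population(growth_law):
    model = RecruitmentModel(
        t0_true=0.25, rise_width=0.2, plateau_fraction=0.6, noise_cv=0.1
    )
    return simulate_population(800, growth_law, model, seed=11)
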