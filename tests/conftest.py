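import numpy as np
import pytest

from spdharm import Cohort, SimulationConfig, Subject, generate_cohort


def random_spd(rng: np.random.Generator, n: int,
               cond_scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix via A A^T + n I scaling."""
    A = rng.normal(size=(n, n)) * cond_scale
    return A @ A.T + n * np.eye(n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def spd_pair(rng):
    return random_spd(rng, 5), random_spd(rng, 5)


@pytest.fixture
def small_cohort() -> Cohort:
    """Two-site, two-condition cohort of 3x3 matrices, deterministic."""
    synthetic = generate_cohort(SimulationConfig(
        dim=3, n_sites=2, n_per_site_per_condition=3,
        site_scale=0.4, site_dispersion=0.15, seed=7))
    return synthetic.cohort


@pytest.fixture
def biased_cohort():
    """Site-biased cohort with unequal dispersions, no condition effect."""
    return generate_cohort(SimulationConfig(
        dim=8, n_sites=3, n_per_site_per_condition=5,
        site_scale=0.5, site_dispersion=(0.05, 0.15, 0.3), seed=21))
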