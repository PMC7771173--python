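import numpy as np
import pytest

import stoichscape as ss


@pytest.fixture(scope="session")
def small_landscape():
    """A 200x200 correlated C/N landscape pair on the pooled targets."""
    return ss.simulate_elemental_pair(
        200, 200, target_corr=-0.01, spatial_range=90.0, seed=101
    )


@pytest.fixture(scope="session")
def movement_kernel():
    return ss.MovementModel(gamma_shape=2.0, gamma_scale=150.0, vm_mu=0.0, vm_kappa=0.5)


@pytest.fixture(scope="session")
def tiny_fixture_dataset():
    """A small deterministic two-area dataset for pipeline-level tests."""
    return ss.make_fixture_dataset(seed=11, n_animals_per_area=2, n_fixes=400, grid_size=120)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
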