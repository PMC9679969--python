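import numpy as np
import pytest

from ligmodes.synthdata import (
    SyntheticComplexSpec,
    build_pet_tetramer,
    make_synthetic_trajectory,
    make_toy_structure,
)

LIGAND = ["PTE"]


@pytest.fixture(scope="session")
def tetramer():
    return build_pet_tetramer()


@pytest.fixture(scope="session")
def toy_structure():
    """Helix scaffold with two disulfides, a catalytic triad and two Na+ sites."""
    return make_toy_structure(
        n_residues=60,
        with_disulfides=[(10, 40), (20, 50)],
        with_triad=True,
        with_ion_sites=[6, ([5, 7, 9], 3)],
        seed=7,
    )


@pytest.fixture(scope="session")
def two_mode_traj():
    """Noise-free two-mode trajectory with disjoint planted contact sets."""
    spec = SyntheticComplexSpec(
        n_modes=2, frames=60, dwell=10, jitter_sigma=0.0, contact_prob=1.0, seed=11
    )
    return make_synthetic_trajectory(spec)


@pytest.fixture(scope="session")
def static_traj():
    """Single planted pose, no jitter: every frame identical in contacts."""
    spec = SyntheticComplexSpec(
        n_modes=1, frames=12, jitter_sigma=0.0, contact_prob=1.0, seed=3
    )
    return make_synthetic_trajectory(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
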