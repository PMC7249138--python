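import numpy as np
import pytest

from pepassembly import A6K, make_motif, make_system


@pytest.fixture(scope="session")
def a6k():
    return A6K


@pytest.fixture(scope="session")
def helix_chain():
    return make_motif(A6K, "alpha_helix")


@pytest.fixture(scope="session")
def extended_chain():
    return make_motif(A6K, "extended")


@pytest.fixture(scope="session")
def turn2_chain():
    """beta_turn_II planted at window 3..6."""
    return make_motif(A6K, "beta_turn_II", turn_position=3)


@pytest.fixture(scope="session")
def micellar_system():
    return make_system(
        A6K, 12, box_nm=8.0, placement="micellar", seed=1,
        per_chain_motif="beta_turn_II",
    )


@pytest.fixture(scope="session")
def dispersed_system():
    return make_system(
        A6K, 12, box_nm=8.0, placement="dispersed", min_dist_A=4.0, seed=7
    )


def rigid_transform(rng=None):
    """A random rotation + translation for invariance checks."""
    rng = rng or np.random.default_rng(123)
    from pepassembly.geometry import random_rotation

    return random_rotation(rng), rng.uniform(-30, 30, size=3)
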