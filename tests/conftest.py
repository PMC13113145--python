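import numpy as np
import pytest

from pepdiff.denoiser import DenoiserConfig, PepDiffModel
from pepdiff.diffusion import make_schedule
from pepdiff.fixtures import FixtureSpec, make_ideal_chain, make_toy_complex
from pepdiff.internal_coords import ResidueAngleTable


def random_angle_table(length: int, rng: np.random.Generator) -> ResidueAngleTable:
    """A physically valid random angle table (torsions free, bond angles
    in a realistic band)."""
    angles = np.empty((length, 6))
    angles[:, :3] = rng.uniform(-np.pi, np.pi, (length, 3))
    angles[:, 3:] = rng.uniform(1.5, 2.6, (length, 3))
    return ResidueAngleTable.from_angles(angles)


@pytest.fixture(scope="session")
def helix_chain():
    return make_ideal_chain("helix", 12, seed=0)


@pytest.fixture(scope="session")
def strand_chain():
    return make_ideal_chain("strand", 12, seed=0)


@pytest.fixture(scope="session")
def toy_pair():
    return make_toy_complex(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def reduced_model():
    return PepDiffModel(DenoiserConfig.reduced(parameter_seed=5))


@pytest.fixture(scope="session")
def short_schedule():
    return make_schedule("linear", T=100)
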