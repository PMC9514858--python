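import numpy as np
import pytest

from vnarens.structio import RegionMap, default_vnar_region_map
from vnarens.synthetic import build_toy_peptide, make_humanization_scenario


@pytest.fixture(scope="session")
def region_map() -> RegionMap:
    return default_vnar_region_map()


@pytest.fixture(scope="session")
def small_scenario():
    """Cheap parent/variant ensemble pair for structural (non-recovery) tests."""
    return make_humanization_scenario(n_frames=20_000, seed=11)


@pytest.fixture(scope="session")
def extended_tripeptide():
    """Fully extended 3-residue alanine peptide (phi=-180, psi=180)."""
    torsions = np.full((1, 3, 2), 180.0)
    torsions[:, :, 0] = -180.0
    return build_toy_peptide("AAA", torsions)


@pytest.fixture(scope="session")
def helix_octapeptide():
    """Ideal alpha-helical 8-residue peptide (phi=-57, psi=-47)."""
    torsions = np.tile(np.array([-57.0, -47.0]), (1, 8, 1))
    return build_toy_peptide("A" * 8, torsions)
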