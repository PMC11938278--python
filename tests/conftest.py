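import numpy as np
import pytest

from hydrasite.structure_io import compute_sasa
from hydrasite.synthetic_data import (SyntheticSpec, make_structure,
                                      make_trajectory, plant_sites)


@pytest.fixture(scope="session")
def toy_structure():
    """A small solvated toy structure with SASA computed."""
    structure = make_structure(SyntheticSpec(n_residues=6, seed=42))
    compute_sasa(structure)
    return structure


@pytest.fixture(scope="session")
def planted_case():
    """(structure, planted sites) with occupancies >= 0.5 for loss tests."""
    spec = SyntheticSpec(n_residues=6, seed=7, occupancy_range=(0.5, 1.0),
                         max_sites=8)
    structure = make_structure(spec)
    compute_sasa(structure)
    sites = plant_sites(structure, spec)
    assert len(sites) >= 3
    return structure, sites


@pytest.fixture(scope="session")
def planted_trajectory():
    """(spec, structure, sites, trajectory) for trajectory-analysis tests."""
    spec = SyntheticSpec(n_residues=6, seed=7, n_frames=1000,
                         occupancy_range=(0.5, 1.0), max_sites=6)
    structure = make_structure(spec)
    compute_sasa(structure)
    sites = plant_sites(structure, spec)
    traj = make_trajectory(sites, spec)
    return spec, structure, sites, traj


def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-10, 10, size=3)
    return R, t
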