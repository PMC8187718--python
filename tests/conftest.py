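"""Shared fixtures: small synthetic structures and trajectories."""

import numpy as np
import pytest

from allotrace.structure_io import AtomRecord, Structure, Trajectory
from allotrace.synthetic import StateSpec, SyntheticSpec, build_ideal_helix, generate_trajectory


@pytest.fixture(scope="session")
def ideal_helix() -> Structure:
    return build_ideal_helix(20)


@pytest.fixture(scope="session")
def tripeptide() -> Structure:
    """3-residue backbone fixture with GLY/ALA/GLY names."""
    s = build_ideal_helix(4, phi=-70.0, psi=150.0)
    names = {1: "GLY", 2: "ALA", 3: "GLY", 4: "GLY"}
    atoms = [
        AtomRecord(a.serial, a.name, names[a.residue_id], a.residue_id, a.chain,
                   a.coordinates, a.element)
        for a in s.atoms
        if a.residue_id <= 3
    ]
    return Structure(atoms)


@pytest.fixture(scope="session")
def two_state_traj():
    """50-frame two-state trajectory (0.7/0.3) with well-separated states."""
    spec = SyntheticSpec(
        states=[StateSpec(occupancy=0.7), StateSpec(occupancy=0.3, angle_mean=80.0)],
        n_frames=50, seed=42, noise_sigma=0.1,
    )
    return generate_trajectory(spec)


@pytest.fixture(scope="session")
def single_state_traj():
    """Quiet single-state trajectory for geometry and interaction tests."""
    spec = SyntheticSpec(states=[StateSpec(occupancy=1.0, kink_mean=19.0)],
                         n_frames=8, seed=7, noise_sigma=0.05)
    return generate_trajectory(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
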