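import numpy as np
import pytest

from girkperm import permeation, synthetic
from girkperm.trajectory import Topology, Trajectory


@pytest.fixture
def sf():
    return permeation.SFDefinition(residue_indices=(154, 155, 156, 157, 158))


@pytest.fixture
def toy_spec():
    return synthetic.ToyChannelSpec(duration=100.0, frame_interval=1.0, seed=11)


@pytest.fixture
def traversal_traj(toy_spec):
    scripts = [
        synthetic.PlantedIonScript("K", "traverse_out", 10.0, 70.0),
        synthetic.PlantedIonScript("Na", "loiter_below", 0.0, 100.0),
    ]
    traj, truth = synthetic.generate_toy_trajectory(toy_spec, scripts, n_waters_in_sf=2)
    return traj, truth


def random_trajectory(rng, n_frames=5, n_atoms=8):
    """Unstructured random trajectory for I/O and geometry property tests."""
    top = Topology(
        atom_names=tuple(f"A{i}" for i in range(n_atoms)),
        elements=tuple("C" for _ in range(n_atoms)),
        residue_names=tuple("UNK" for _ in range(n_atoms)),
        residue_indices=tuple(range(n_atoms)),
        chain_ids=tuple("A" for _ in range(n_atoms)),
    )
    coords = rng.normal(0.0, 10.0, (n_frames, n_atoms, 3))
    times = np.arange(n_frames, dtype=float)
    box = np.full((n_frames, 3), 100.0)
    return Trajectory(top, coords, times, box)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
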