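import numpy as np
import pytest

from openring import (RigidTransform, default_q_grid, make_bead_dimer,
                      make_ground_truth_assembly, simulate_profile)

# Scaled-down study conditions shared across tests: a 40-bead-per-protomer
# dimer keeps grid scans fast; the global tilt moves the generator's Euler
# angles away from the Z-Y-Z gimbal lock so all six step parameters are
# individually meaningful.
TILT = RigidTransform.from_euler(20.0, 35.0, 10.0)


@pytest.fixture(scope="session")
def dimer40():
    return make_bead_dimer(n_beads=40, seed=1)


@pytest.fixture(scope="session")
def dimer230():
    return make_bead_dimer(n_beads=230, seed=0)


@pytest.fixture(scope="session")
def truth40(dimer40):
    truth = make_ground_truth_assembly(dimer40, angle_per_unit=55.0, rise=2.0,
                                       radius=40.0, n_units=6, seed=1)
    return truth.transformed(TILT)


@pytest.fixture(scope="session")
def truth230(dimer230):
    return make_ground_truth_assembly(dimer230, angle_per_unit=55.0, rise=2.0,
                                      radius=40.0, n_units=6, seed=0)


@pytest.fixture(scope="session")
def qgrid():
    return default_q_grid()


@pytest.fixture(scope="session")
def noisy_profile40(truth40, qgrid):
    return simulate_profile(truth40.assembly, qgrid, rel_noise=0.02,
                            baseline=0.0, seed=11)


ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00 20.00"
    "           C  \n"
    "END\n"
)

THREE_RES_PDB = (
    "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 10.00"
    "           N  \n"
    "ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00 10.00"
    "           C  \n"
    "ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00 10.00"
    "           C  \n"
    "ATOM      4  N   ALA A   2       3.300   1.500   0.000  1.00 10.00"
    "           N  \n"
    "ATOM      5  CA  ALA A   2       4.100   2.700   0.000  1.00 10.00"
    "           C  \n"
    "ATOM      6  HA  ALA A   2       4.200   3.300   0.900  1.00 10.00"
    "           H  \n"
    "ATOM      7  CA  SER B   3       7.000   5.000   1.000  1.00 10.00"
    "           C  \n"
    "END\n"
)


@pytest.fixture
def one_atom_pdb(tmp_path):
    path = tmp_path / "one_atom.pdb"
    path.write_text(ONE_ATOM_PDB)
    return path


@pytest.fixture
def three_res_pdb(tmp_path):
    path = tmp_path / "three_res.pdb"
    path.write_text(THREE_RES_PDB)
    return path


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation
    return Rotation.from_quat(q).as_matrix()


def random_transform(rng) -> RigidTransform:
    return RigidTransform(random_rotation(rng), rng.uniform(-20, 20, 3))
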