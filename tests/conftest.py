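import numpy as np
import pytest

from vhhassess.pb_alphabet import load_reference_table
from vhhassess.structure_io import DihedralSeries
from vhhassess.synthetic_data import chain_from_dihedrals

# hand-written 3-residue PDB fixture with known coordinates
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.830   0.125  1.00  0.00           C
ATOM      7  C   GLY A   2       5.498   2.649   0.250  1.00  0.00           C
ATOM      8  O   GLY A   2       6.021   1.535   0.250  1.00  0.00           O
ATOM      9  N   SER A   3       6.201   3.770   0.375  1.00  0.00           N
ATOM     10  CA  SER A   3       7.650   3.740   0.500  1.00  0.00           C
ATOM     11  C   SER A   3       8.210   5.150   0.625  1.00  0.00           C
ATOM     12  O   SER A   3       7.470   6.140   0.625  1.00  0.00           O
TER      13
END
"""

CA_FIXTURE = np.array([
    [1.458, 0.000, 0.000],
    [3.988, 2.830, 0.125],
    [7.650, 3.740, 0.500],
])


@pytest.fixture(scope="session")
def pb_table():
    return load_reference_table()


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


def make_helix_chain(length=20, phi=-57.0, psi=-47.0, sequence=None):
    """Ideal-geometry chain with constant interior (phi, psi)."""
    p = np.full(length, float(phi))
    s = np.full(length, float(psi))
    p[0] = np.nan
    s[-1] = np.nan
    return chain_from_dihedrals(DihedralSeries(p, s), sequence or "A" * length)


@pytest.fixture()
def helix_chain():
    return make_helix_chain()


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t


# the seven-segment region map used by synthetic-ensemble tests: a 75-mer
# with a CDR3-like window at positions 51-62
TOY_REGIONS = {
    "FR1": (1, 15), "CDR1": (16, 20), "FR2": (21, 30), "CDR2": (31, 35),
    "FR3": (36, 50), "CDR3": (51, 62), "FR4": (63, 75),
}
TOY_PB_STRING = "d" * 50 + "m" * 12 + "d" * 13
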