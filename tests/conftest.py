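import numpy as np
import pytest

from tuscmorph.structures import Atom, Chain, Residue, Structure
from tuscmorph.synthetic import ToySpokeParams, make_toy_pair


@pytest.fixture(scope="session")
def toy_pair_15():
    """Noise-free two-spoke pair with a 15° tilt of the spoke-2 GRIP2+γ block."""
    return make_toy_pair(ToySpokeParams(tilt_angle=15.0, seed=7))


@pytest.fixture
def three_atom_pdb(tmp_path):
    """Hand-written minimal PDB: one chain, one residue, three atoms."""
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      10.729   5.427  -4.093  1.00  0.00           C\n"
        "TER\nEND\n"
    )
    path = tmp_path / "three_atoms.pdb"
    path.write_text(text)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One CB atom with altlocs A (occ 0.60) and B (occ 0.40)."""
    text = (
        "ATOM      1  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CB ASER A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      3  CB BSER A   1       2.000   0.000   0.000  0.40  0.00           C\n"
        "TER\nEND\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(text)
    return path


def make_chain_from_coords(chain_id, coords, resname="ALA", atom_name="CA", start=1):
    residues = [
        Residue(resname, start + i, atoms=[Atom(atom_name, "C", np.asarray(c, dtype=float))])
        for i, c in enumerate(coords)
    ]
    return Chain(chain_id, residues)


def make_structure(label, chains):
    return Structure(label, chains)
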