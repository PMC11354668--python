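import numpy as np
import pytest

from fcscreen.structure import (
    Atom,
    ComplexStructure,
    Residue,
    assign_regions,
    default_region_map,
    residue_kind,
)


def make_residue(chain_id, seq_num, name, coords_list):
    """One residue from a list of (atom_name, element, xyz) or bare xyz tuples."""
    atoms = []
    for item in coords_list:
        if len(item) == 3 and not isinstance(item[0], str):
            atoms.append(Atom(name="X", element="C", coords=tuple(float(v) for v in item)))
        else:
            an, el, xyz = item
            atoms.append(Atom(name=an, element=el, coords=tuple(float(v) for v in xyz)))
    return Residue(chain_id, seq_num, name, residue_kind(name), atoms)


def make_pair_complex(distance, lig_name="DG", rec_name="ALA", rec_chain="B", rec_seq=250):
    """Minimal complex: one receptor residue at origin, one base at x=distance."""
    rec = make_residue(rec_chain, rec_seq, rec_name, [(0.0, 0.0, 0.0)])
    lig = make_residue("L", 1, lig_name, [(float(distance), 0.0, 0.0)])
    return ComplexStructure(
        complex_id="pair",
        receptor_chains={rec_chain: [rec]},
        ligand_chain=[lig],
        glycan_chains={},
    )


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  CA  ALA B 250      10.000  10.000  10.000  1.00  0.00           C
ATOM      2  P    DG L   1      12.000  10.000  10.000  1.00  0.00           P
HETATM    3  C1  NAG E   1      30.000  30.000  30.000  1.00  0.00           C
END
"""

TWO_DNA_CHAIN_PDB = """\
ATOM      1  CA  ALA B 250      10.000  10.000  10.000  1.00  0.00           C
ATOM      2  P    DG L   1      12.000  10.000  10.000  1.00  0.00           P
ATOM      3  P    DT M   1      50.000  10.000  10.000  1.00  0.00           P
END
"""


@pytest.fixture
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture
def two_dna_chain_pdb_text():
    return TWO_DNA_CHAIN_PDB
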