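import numpy as np
import pytest

from diffcontact import (
    DCMParameters,
    Atom,
    Residue,
    StructureModel,
    align_sequences,
    build_residue_map,
    compute_contact_map,
    difference_map,
    filter_difference_map,
    identify_dsrs,
    parse_structure,
)

THREE_ALA_PDB = """\
HEADER    FIXTURE
SEQRES   1 A    3  ALA ALA ALA
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.500   2.000   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.000   0.000   1.500  1.00  0.00           C
ATOM      6  N   ALA A   2       3.800   1.000   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       4.800   0.000   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.800   1.000   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.300   2.000   0.000  1.00  0.00           O
ATOM     10  CB  ALA A   2       4.800   0.000   1.500  1.00  0.00           C
ATOM     11  N   ALA A   3       7.600   1.000   0.000  1.00  0.00           N
ATOM     12  CA  ALA A   3       8.600   0.000   0.000  1.00  0.00           C
ATOM     13  C   ALA A   3       9.600   1.000   0.000  1.00  0.00           C
ATOM     14  O   ALA A   3      10.100   2.000   0.000  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.600   0.000   1.500  1.00  0.00           C
TER
END
"""


@pytest.fixture
def three_ala_pdb():
    return THREE_ALA_PDB


def make_residue(name, seq_id, sidechain_coords=(), backbone_origin=(0.0, 0.0, 0.0)):
    """In-memory residue with a standard backbone and given side-chain atoms."""
    o = np.asarray(backbone_origin, dtype=float)
    atoms = [
        Atom("N", "N", o + (-1.2, 0.9, 0.0)),
        Atom("CA", "C", o),
        Atom("C", "C", o + (1.2, 0.9, 0.0)),
        Atom("O", "O", o + (1.4, 2.0, 0.0)),
    ]
    sidechain_names = ["CB", "CG", "CD", "CE", "CZ", "CH"]
    for k, xyz in enumerate(sidechain_coords):
        atoms.append(Atom(sidechain_names[k], "C", np.asarray(xyz, dtype=float)))
    return Residue(name=name, seq_id=seq_id, atoms=atoms, label_seq=seq_id)


def make_chain_model(sidechain_positions, label="toy", names=None):
    """Model whose residue k has one side-chain atom at the given position."""
    names = names or ["ALA"] * len(sidechain_positions)
    residues = [
        make_residue(names[k], k + 1, sidechain_coords=[xyz], backbone_origin=np.asarray(xyz) + (0, 5, 0))
        for k, xyz in enumerate(sidechain_positions)
    ]
    seqres = "".join({"ALA": "A", "GLY": "G", "VAL": "V"}.get(n, "X") for n in names)
    return StructureModel(pdb_id=label, chain_id="A", residues=residues, seqres=seqres)


def run_core(model_a, model_b, params=DCMParameters()):
    """Parse-free pipeline core: residue map -> filtered DCM -> DSRs."""
    aln = align_sequences(model_a.seqres, model_b.seqres)
    rmap = build_residue_map(aln, model_a, model_b)
    cm_a = compute_contact_map(model_a, rmap, "A_only", params)
    cm_b = compute_contact_map(model_b, rmap, "B_only", params)
    dcm = filter_difference_map(difference_map(cm_a, cm_b, model_a, model_b, rmap, params), params)
    dsrs = identify_dsrs(dcm, model_a, model_b, rmap)
    return rmap, cm_a, cm_b, dcm, dsrs


def run_core_on_texts(text_a, text_b, params=DCMParameters()):
    model_a = parse_structure(text_a, "A", pdb_id="a")
    model_b = parse_structure(text_b, "A", pdb_id="b")
    return (model_a, model_b) + run_core(model_a, model_b, params)
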