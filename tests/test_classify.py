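"""Atom classification: rule-derived table, lookups, fallbacks."""

import numpy as np
import pytest

from yrb.classify import (
    AtomClass,
    Provenance,
    build_standard_table,
    class_composition,
    classify_atom,
    classify_structure,
    infer_bonds,
)
from yrb.fixtures import build_peptide, build_residue
from yrb.model import Atom, Chain, Residue, StructureModel
from yrb.topology import RESIDUE_TOPOLOGIES, STANDARD_AMINO_ACIDS

H, NEG, POS, W = (
    AtomClass.HYDROPHOBIC,
    AtomClass.NEGATIVE,
    AtomClass.POSITIVE,
    AtomClass.NEUTRAL,
)

# Hand-derived side-chain classes, written out from the literal rule
# (carbon yellow iff no bonded N/O; Asp/Glu carboxylate O red; Lys/Arg
# charged N blue; everything else white).  Backbone N/CA/C/O and OXT are
# white for every residue and asserted separately.
HAND_TABLE = {
    "ALA": {"CB": H},
    "ARG": {"CB": H, "CG": H, "CD": W, "NE": POS, "CZ": W, "NH1": POS, "NH2": POS},
    "ASN": {"CB": H, "CG": W, "OD1": W, "ND2": W},
    "ASP": {"CB": H, "CG": W, "OD1": NEG, "OD2": NEG},
    "CYS": {"CB": H, "SG": W},
    "GLN": {"CB": H, "CG": H, "CD": W, "OE1": W, "NE2": W},
    "GLU": {"CB": H, "CG": H, "CD": W, "OE1": NEG, "OE2": NEG},
    "GLY": {},
    "HIS": {"CB": H, "CG": W, "ND1": W, "CD2": W, "CE1": W, "NE2": W},
    "ILE": {"CB": H, "CG1": H, "CG2": H, "CD1": H},
    "LEU": {"CB": H, "CG": H, "CD1": H, "CD2": H},
    "LYS": {"CB": H, "CG": H, "CD": H, "CE": W, "NZ": POS},
    "MET": {"CB": H, "CG": H, "SD": W, "CE": H},
    "PHE": {"CB": H, "CG": H, "CD1": H, "CD2": H, "CE1": H, "CE2": H, "CZ": H},
    "PRO": {"CB": H, "CG": H, "CD": W},
    "SER": {"CB": W, "OG": W},
    "THR": {"CB": W, "OG1": W, "CG2": H},
    "TRP": {
        "CB": H, "CG": H, "CD1": W, "CD2": H, "NE1": W, "CE2": W,
        "CE3": H, "CZ2": H, "CZ3": H, "CH2": H,
    },
    "TYR": {"CB": H, "CG": H, "CD1": H, "CD2": H, "CE1": H, "CE2": H, "CZ": W, "OH": W},
    "VAL": {"CB": H, "CG1": H, "CG2": H},
}


def test_table_matches_hand_derivation(table):
    """The generated table equals the hand-derived one atom-for-atom."""
    for code in STANDARD_AMINO_ACIDS:
        expected = dict(HAND_TABLE[code])
        for backbone in ("N", "CA", "C", "O", "OXT"):
            expected[backbone] = W
        assert table.residue_entries(code) == expected, code


@pytest.mark.parametrize(
    ("residue", "atom", "expected"),
    [
        ("ARG", "CG", H),
        ("ARG", "NE", POS),
        ("ARG", "NH1", POS),
        ("ARG", "NH2", POS),
        ("SER", "CB", W),
        ("THR", "CB", W),
        ("THR", "CG2", H),
        ("HIS", "ND1", W),
        ("HIS", "NE2", W),
        ("GLU", "OE1", NEG),
        ("GLY", "CA", W),
        ("LYS", "CE", W),
        ("LYS", "CD", H),
        ("ARG", "CD", W),
        ("TRP", "CD1", W),
        ("TRP", "CE3", H),
        ("TYR", "CZ", W),
        ("PRO", "CD", W),
    ],
)
def test_spot_checks(table, residue, atom, expected):
    assert classify_atom(residue, atom, table) is expected


def test_absent_key_is_unclassified(table):
    assert classify_atom("XYZ", "C1", table) is AtomClass.UNCLASSIFIED


def test_charged_classes_are_restricted(table):
    """NEGATIVE only on Asp/Glu carboxylate O; POSITIVE only on Lys/Arg N;
    no non-carbon atom is ever hydrophobic; His contributes no charge."""
    for (code, atom), cls in table.entries.items():
        if cls is NEG:
            assert (code, atom) in {
                ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")
            }
        if cls is POS:
            assert (code, atom) in {
                ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")
            }
        if cls is H:
            assert atom[0] == "C" and atom not in ("CL",)
        if code == "HIS":
            assert cls in (H, W)


def test_infer_bonds_distance_cutoff():
    res = Residue("UNK", 1)
    res.atoms.append(Atom(1, "C1", "C", [0.0, 0.0, 0.0]))
    res.atoms.append(Atom(2, "C2", "C", [1.54, 0.0, 0.0]))
    res.atoms.append(Atom(3, "C3", "C", [1.54 + 2.60, 0.0, 0.0]))
    topo = infer_bonds(res)
    assert topo.bonded("C1", "C2")
    assert not topo.bonded("C2", "C3")


def test_infer_bonds_requires_element():
    res = Residue("UNK", 1)
    res.atoms.append(Atom(1, "Q1", "", [0, 0, 0]))
    with pytest.raises(ValueError, match="Q1"):
        infer_bonds(res)


@pytest.mark.parametrize("code", STANDARD_AMINO_ACIDS)
def test_bond_inference_agrees_with_table_on_standard_residues(code, table):
    """Geometry fallback reproduces the table for carbons of every residue."""
    res = build_residue(code)
    topo = infer_bonds(res)
    assert topo.bonds == RESIDUE_TOPOLOGIES[code].bonds
    for atom in res.atoms:
        carbon_rule = topo.elements[atom.name] == "C" and all(
            topo.elements[nb] not in ("N", "O") for nb in topo.neighbors(atom.name)
        )
        table_cls = table.lookup(code, atom.name)
        assert carbon_rule == (table_cls is H)


def test_classify_structure_matches_table(twenty_mer, twenty_mer_classified, table):
    for chain, residue, atom in twenty_mer.iter_atoms():
        key = (chain.chain_id, residue.seq_id, residue.insertion_code, atom.name)
        assert twenty_mer_classified.classes[key] is table.lookup(
            residue.name, atom.name
        )
        assert twenty_mer_classified.provenance[key] is Provenance.TABLE


def test_hetero_compound_neutral_by_default():
    res = Residue("ADP", 500)
    for i, (name, el) in enumerate(
        [("PA", "P"), ("O1A", "O"), ("C5'", "C"), ("N9", "N")], start=1
    ):
        res.atoms.append(
            Atom(i, name, el, [2.0 * i, 0, 0], is_hetero=True)
        )
    model = StructureModel("adp", [Chain("A", [res])])
    classified = classify_structure(model)
    assert set(classified.classes.values()) == {W}
    assert set(classified.provenance.values()) == {Provenance.POLICY_DEFAULT}


def test_selenomethionine_bond_inference_fallback():
    """MSE carbons bonded only to C/S/Se stay hydrophobic under inference."""
    met = build_residue("MET")
    mse = Residue("MSE", 1)
    for atom in met.atoms:
        name = "SE" if atom.name == "SD" else atom.name
        element = "SE" if atom.name == "SD" else atom.element
        mse.atoms.append(Atom(atom.serial, name, element, atom.coords))
    model = StructureModel("mse", [Chain("A", [mse])])
    classified = classify_structure(model, fallback="bond-inference")
    get = lambda n: classified.classes[("A", 1, "", n)]
    assert get("CB") is H and get("CG") is H and get("CE") is H
    assert get("SE") is W and get("N") is W
    assert classified.provenance[("A", 1, "", "CB")] is Provenance.BOND_INFERENCE


def test_nonstandard_fallback_never_charged():
    asp = build_residue("ASP")
    odd = Residue("XAS", 1)  # ASP geometry under a non-standard name
    for atom in asp.atoms:
        odd.atoms.append(Atom(atom.serial, atom.name, atom.element, atom.coords))
    model = StructureModel("x", [Chain("A", [odd])])
    classified = classify_structure(model, fallback="bond-inference")
    assert NEG not in classified.classes.values()
    assert POS not in classified.classes.values()
    # carboxylate oxygens become neutral, CB stays hydrophobic
    assert classified.classes[("A", 1, "", "OD1")] is W
    assert classified.classes[("A", 1, "", "CB")] is H


def test_fallback_skip_leaves_unclassified():
    odd = Residue("XXX", 1)
    odd.atoms.append(Atom(1, "C1", "C", [0, 0, 0]))
    model = StructureModel("x", [Chain("A", [odd])])
    classified = classify_structure(model, fallback="skip")
    assert classified.classes[("A", 1, "", "C1")] is AtomClass.UNCLASSIFIED


def test_class_composition_examples(table):
    ala = build_peptide(["ALA"])  # includes OXT
    model = StructureModel("ala", [ala])
    counts = class_composition(classify_structure(model, table))
    assert counts[H] == 1 and counts[W] == 5
    assert sum(counts.values()) == model.n_atoms

    arg = build_residue("ARG")
    arg.atoms = [a for a in arg.atoms if a.name not in ("N", "CA", "C", "O")]
    counts = class_composition(classify_structure(StructureModel("r", [Chain("A", [arg])])))
    assert counts[H] == 2 and counts[POS] == 3 and counts[W] == 2

    empty = class_composition(classify_structure(StructureModel("e", [])))
    assert all(v == 0 for v in empty.values())


def test_charged_termini_flag():
    model = StructureModel("p", [build_peptide(["ALA", "GLY"])])
    classified = classify_structure(model, charged_termini=True)
    assert classified.classes[("A", 1, "", "N")] is POS
    assert classified.classes[("A", 2, "", "OXT")] is NEG
    assert classified.classes[("A", 2, "", "O")] is NEG
    default = classify_structure(model)
    assert default.classes[("A", 1, "", "N")] is W
    assert default.classes[("A", 2, "", "OXT")] is W
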