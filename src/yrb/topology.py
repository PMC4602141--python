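"""Idealized heavy-atom connectivity for the 20 standard amino acids.

Each residue is a small covalent bond graph over PDB v3 atom names.  The
backbone (N-CA-CA-C-C=O) is shared; side-chain bonds are listed per
residue.  This connectivity is what the atom-typing rule operates on:
a carbon is "hydrophobic" exactly when none of its covalent neighbours
is nitrogen or oxygen, so the bond list — not any coordinate — decides
the class.  Inter-residue peptide bonds (C(i)-N(i+1)) involve only
backbone atoms that the rule colours white anyway, so per-residue graphs
are sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS",
    "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO",
    "SER", "THR", "TRP", "TYR", "VAL",
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BACKBONE_BONDS = (("N", "CA"), ("CA", "C"), ("C", "O"))

# Side-chain bonds per residue (heavy atoms only).  CB always attaches to CA.
_SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "GLY": (),
    "ALA": (("CA", "CB"),),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "PHE": (
        ("CA", "CB"), ("CB", "CG"),
        ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
        ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
    ),
    "TYR": (
        ("CA", "CB"), ("CB", "CG"),
        ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
        ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
        ("CZ", "OH"),
    ),
    "TRP": (
        ("CA", "CB"), ("CB", "CG"),
        ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"),
        ("CE2", "CD2"), ("CD2", "CG"),
        ("CE2", "CZ2"), ("CZ2", "CH2"), ("CH2", "CZ3"),
        ("CZ3", "CE3"), ("CE3", "CD2"),
    ),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "HIS": (
        ("CA", "CB"), ("CB", "CG"),
        ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
        ("NE2", "CD2"), ("CD2", "CG"),
    ),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "ARG": (
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
        ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
    ),
}


def element_of(atom_name: str) -> str:
    """Element of a standard-residue heavy atom from its PDB name.

    PDB v3 protein atom names start with the element symbol; for the
    standard amino acids the first character suffices (C/N/O/S) except
    selenium in MSE-like names ("SE").
    """
    name = atom_name.strip()
    if name.upper().startswith("SE"):
        return "SE"
    return name[0].upper()


@dataclass(frozen=True)
class ResidueTopology:
    """Heavy atoms plus symmetric covalent bond set for one residue type."""

    residue_code: str
    atoms: tuple[str, ...]
    elements: dict[str, str] = field(hash=False)
    bonds: frozenset[frozenset[str]] = field(hash=False)

    def neighbors(self, atom_name: str) -> set[str]:
        out: set[str] = set()
        for bond in self.bonds:
            if atom_name in bond:
                out.update(bond - {atom_name})
        return out

    def bonded(self, a: str, b: str) -> bool:
        return frozenset({a, b}) in self.bonds


def _build(code: str) -> ResidueTopology:
    bonds = set(BACKBONE_BONDS) | set(_SIDE_CHAIN_BONDS[code])
    atoms: list[str] = list(BACKBONE_ATOMS)
    for a, b in _SIDE_CHAIN_BONDS[code]:
        for name in (a, b):
            if name not in atoms:
                atoms.append(name)
    return ResidueTopology(
        residue_code=code,
        atoms=tuple(atoms),
        elements={a: element_of(a) for a in atoms},
        bonds=frozenset(frozenset(p) for p in bonds),
    )


#: code -> idealized topology, all 20 standard residues.
RESIDUE_TOPOLOGIES: dict[str, ResidueTopology] = {
    code: _build(code) for code in STANDARD_AMINO_ACIDS
}
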