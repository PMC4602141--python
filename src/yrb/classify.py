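"""YRB atom classification: hydrophobic / negative / positive / neutral.

The scheme types every heavy atom of a protein by local chemistry:

* **HYDROPHOBIC** (yellow) — a carbon none of whose covalent neighbours
  is nitrogen or oxygen.  Such CHn groups carry no polar substitution
  and can engage in hydrophobic contacts.
* **NEGATIVE** (red) — the carboxylate oxygens of Asp (OD1/OD2) and
  Glu (OE1/OE2), charged at physiological pH.
* **POSITIVE** (blue) — the charged side-chain nitrogens of Lys (NZ)
  and Arg (NE/NH1/NH2).
* **NEUTRAL** (white) — everything else, including the polar backbone
  (N, CA, C, O) and all of histidine, which is treated as uncharged.

For the 20 standard residues the classes come from a precomputed lookup
table generated by applying the carbon rule to idealized residue bond
graphs.  Non-standard polymer residues fall back to distance-based bond
inference and the carbon rule alone (never a charged class); hetero
compounds and waters default to NEUTRAL.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from io import StringIO
from itertools import combinations
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .model import COVALENT_RADII, Atom, Residue, StructureModel, atom_key, AtomKey
from .topology import (
    RESIDUE_TOPOLOGIES,
    STANDARD_AMINO_ACIDS,
    ResidueTopology,
)

#: Slack added to the sum of covalent radii when inferring bonds (Angstrom).
BOND_TOLERANCE = 0.45

#: Side-chain atoms carrying formal charge at physiological pH.
NEGATIVE_ATOMS = frozenset({("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")})
POSITIVE_ATOMS = frozenset({("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")})


class AtomClass(enum.Enum):
    HYDROPHOBIC = "hydrophobic"  # yellow
    NEGATIVE = "negative"        # red
    POSITIVE = "positive"        # blue
    NEUTRAL = "neutral"          # white
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # compact in reports
        return self.value


class Provenance(enum.Enum):
    TABLE = "table"
    BOND_INFERENCE = "bond-inference"
    POLICY_DEFAULT = "policy-default"


@dataclass(frozen=True)
class ClassificationTable:
    """(residue code, atom name) -> AtomClass for standard residues."""

    entries: dict[tuple[str, str], AtomClass]

    def lookup(self, residue_code: str, atom_name: str) -> AtomClass:
        return self.entries.get((residue_code, atom_name), AtomClass.UNCLASSIFIED)

    def residue_entries(self, residue_code: str) -> dict[str, AtomClass]:
        return {
            atom: cls
            for (code, atom), cls in self.entries.items()
            if code == residue_code
        }


def _carbon_rule(topology: ResidueTopology, atom_name: str) -> bool:
    """True iff the atom is a carbon with no bonded N or O."""
    if topology.elements[atom_name] != "C":
        return False
    return all(
        topology.elements[nb] not in ("N", "O") for nb in topology.neighbors(atom_name)
    )


def build_standard_table() -> ClassificationTable:
    """Generate the standard-residue table by applying the rule to bond graphs.

    Backbone N/CA/C/O are white by the same rule (CA is bonded to N, C to
    O), so no special-casing is needed beyond the charged-atom lists.
    OXT is included as NEUTRAL for every residue (the neutral-termini
    default; see :func:`classify_structure` for the charged-termini option).
    """
    entries: dict[tuple[str, str], AtomClass] = {}
    for code in STANDARD_AMINO_ACIDS:
        topo = RESIDUE_TOPOLOGIES[code]
        for atom in topo.atoms:
            if (code, atom) in NEGATIVE_ATOMS:
                cls = AtomClass.NEGATIVE
            elif (code, atom) in POSITIVE_ATOMS:
                cls = AtomClass.POSITIVE
            elif _carbon_rule(topo, atom):
                cls = AtomClass.HYDROPHOBIC
            else:
                cls = AtomClass.NEUTRAL
            entries[(code, atom)] = cls
        entries[(code, "OXT")] = AtomClass.NEUTRAL
    return ClassificationTable(entries=entries)


def classify_atom(
    residue_code: str, atom_name: str, table: ClassificationTable
) -> AtomClass:
    """Exact table lookup; absent keys yield UNCLASSIFIED."""
    return table.lookup(residue_code, atom_name)


def infer_bonds(residue: Residue) -> ResidueTopology:
    """Distance-based covalent bond inference within one residue.

    Two heavy atoms are bonded iff their separation does not exceed the
    sum of their covalent radii plus ``BOND_TOLERANCE``.  Used as the
    classification fallback for residues outside the standard table.
    """
    atoms = residue.atoms
    if not atoms:
        raise ValueError(f"residue {residue.name} {residue.seq_id}: no atoms")
    elements: dict[str, str] = {}
    for atom in atoms:
        if not atom.element:
            raise ValueError(
                f"residue {residue.name} {residue.seq_id}: atom {atom.name!r} "
                "has no element; cannot infer bonds"
            )
        elements[atom.name] = atom.element
    bonds: set[frozenset[str]] = set()
    for a, b in combinations(atoms, 2):
        ra = COVALENT_RADII.get(a.element)
        rb = COVALENT_RADII.get(b.element)
        if ra is None or rb is None:
            missing = a.name if ra is None else b.name
            raise ValueError(
                f"residue {residue.name} {residue.seq_id}: no covalent radius "
                f"for atom {missing!r} (element {elements[missing]!r})"
            )
        if a.distance_to(b) <= ra + rb + BOND_TOLERANCE:
            bonds.add(frozenset({a.name, b.name}))
    return ResidueTopology(
        residue_code=residue.name,
        atoms=tuple(a.name for a in atoms),
        elements=elements,
        bonds=frozenset(bonds),
    )


@dataclass
class ClassifiedStructure:
    """A structure together with its per-atom class and provenance maps."""

    model: StructureModel
    classes: dict[AtomKey, AtomClass] = field(default_factory=dict)
    provenance: dict[AtomKey, Provenance] = field(default_factory=dict)

    def atom_class(self, key: AtomKey) -> AtomClass:
        return self.classes[key]


FALLBACK_POLICIES = ("bond-inference", "neutral", "skip")


def classify_structure(
    model: StructureModel,
    table: ClassificationTable | None = None,
    fallback: str = "bond-inference",
    charged_termini: bool = False,
) -> ClassifiedStructure:
    """Assign a YRB class to every heavy atom of the model.

    Standard residues go through the lookup table.  Non-standard polymer
    residues are handled per ``fallback``:

    * ``"bond-inference"`` — infer covalent bonds from geometry and apply
      only the carbon rule (carbon HYDROPHOBIC iff no bonded N/O,
      everything else NEUTRAL; never a charged class),
    * ``"neutral"`` — everything NEUTRAL,
    * ``"skip"`` — left UNCLASSIFIED.

    Hetero compounds (ligands, waters, ions) are NEUTRAL under the
    default policy: they sit outside the amino-acid scheme.

    ``charged_termini`` optionally marks terminal carboxylate oxygens
    (OXT and the last residue's O) NEGATIVE and the N-terminal backbone
    nitrogen POSITIVE, reflecting the zwitterionic state at
    physiological pH.
    """
    if fallback not in FALLBACK_POLICIES:
        raise ValueError(f"unknown fallback policy {fallback!r}; use one of {FALLBACK_POLICIES}")
    if table is None:
        table = build_standard_table()

    classified = ClassifiedStructure(model=model)
    for chain in model.chains:
        for residue in chain.residues:
            standard = residue.name in RESIDUE_TOPOLOGIES
            if standard:
                for atom in residue.atoms:
                    key = atom_key(chain, residue, atom)
                    cls = table.lookup(residue.name, atom.name)
                    if cls is AtomClass.UNCLASSIFIED:
                        # unexpected atom name inside a standard residue
                        cls, prov = _fallback_class(residue, atom, fallback)
                    else:
                        prov = Provenance.TABLE
                    classified.classes[key] = cls
                    classified.provenance[key] = prov
            elif residue.is_hetero:
                for atom in residue.atoms:
                    key = atom_key(chain, residue, atom)
                    classified.classes[key] = AtomClass.NEUTRAL
                    classified.provenance[key] = Provenance.POLICY_DEFAULT
            else:
                _classify_nonstandard(classified, chain, residue, fallback)

    if charged_termini:
        _apply_charged_termini(classified)
    return classified


def _fallback_class(
    residue: Residue, atom: Atom, fallback: str
) -> tuple[AtomClass, Provenance]:
    if fallback == "neutral":
        return AtomClass.NEUTRAL, Provenance.POLICY_DEFAULT
    if fallback == "skip":
        return AtomClass.UNCLASSIFIED, Provenance.POLICY_DEFAULT
    topo = infer_bonds(residue)
    if topo.elements[atom.name] == "C" and all(
        topo.elements[nb] not in ("N", "O") for nb in topo.neighbors(atom.name)
    ):
        return AtomClass.HYDROPHOBIC, Provenance.BOND_INFERENCE
    return AtomClass.NEUTRAL, Provenance.BOND_INFERENCE


def _classify_nonstandard(
    classified: ClassifiedStructure, chain, residue: Residue, fallback: str
) -> None:
    if fallback == "neutral":
        for atom in residue.atoms:
            key = atom_key(chain, residue, atom)
            classified.classes[key] = AtomClass.NEUTRAL
            classified.provenance[key] = Provenance.POLICY_DEFAULT
        return
    if fallback == "skip":
        for atom in residue.atoms:
            key = atom_key(chain, residue, atom)
            classified.classes[key] = AtomClass.UNCLASSIFIED
            classified.provenance[key] = Provenance.POLICY_DEFAULT
        return
    topo = infer_bonds(residue)
    for atom in residue.atoms:
        key = atom_key(chain, residue, atom)
        hydrophobic = topo.elements[atom.name] == "C" and all(
            topo.elements[nb] not in ("N", "O") for nb in topo.neighbors(atom.name)
        )
        classified.classes[key] = (
            AtomClass.HYDROPHOBIC if hydrophobic else AtomClass.NEUTRAL
        )
        classified.provenance[key] = Provenance.BOND_INFERENCE


def _apply_charged_termini(classified: ClassifiedStructure) -> None:
    for chain in classified.model.chains:
        polymer = [r for r in chain.residues if r.name in RESIDUE_TOPOLOGIES]
        if not polymer:
            continue
        first, last = polymer[0], polymer[-1]
        for residue, names, cls in (
            (first, ("N",), AtomClass.POSITIVE),
            (last, ("OXT", "O"), AtomClass.NEGATIVE),
        ):
            for name in names:
                if residue.has_atom(name):
                    key = (chain.chain_id, residue.seq_id, residue.insertion_code, name)
                    classified.classes[key] = cls
                    classified.provenance[key] = Provenance.POLICY_DEFAULT


def class_composition(classified: ClassifiedStructure) -> dict[AtomClass, int]:
    """Per-class atom counts; always contains every class as a key."""
    counts = {cls: 0 for cls in AtomClass}
    for cls in classified.classes.values():
        counts[cls] += 1
    return counts


def export_json(classified: ClassifiedStructure) -> str:
    """Class map as a JSON array of per-atom records."""
    records = [
        {
            "chain": ch,
            "resid": seq,
            "icode": icode,
            "resname": _resname(classified.model, ch, seq, icode),
            "atom": name,
            "class": str(classified.classes[(ch, seq, icode, name)]),
            "provenance": classified.provenance[(ch, seq, icode, name)].value,
        }
        for (ch, seq, icode, name) in sorted(classified.classes)
    ]
    return json.dumps(records, indent=2)


def export_tsv(classified: ClassifiedStructure) -> str:
    buf = StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["chain", "resid", "icode", "resname", "atom", "class", "provenance"])
    for key in sorted(classified.classes):
        ch, seq, icode, name = key
        writer.writerow([
            ch, seq, icode,
            _resname(classified.model, ch, seq, icode),
            name,
            str(classified.classes[key]),
            classified.provenance[key].value,
        ])
    return buf.getvalue()


def _resname(model: StructureModel, chain_id: str, seq_id: int, icode: str) -> str:
    return model.chain(chain_id).residue(seq_id, icode).name
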