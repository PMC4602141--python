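"""Hierarchical structure model: chains -> residues -> atoms.

A deliberately small, mutable container tuned for atom-typing and
geometry work: one coordinate model, heavy atoms only after
preparation, altlocs already resolved.  Parsing from PDB/mmCIF lives in
:mod:`yrb.io`; this module owns only the in-memory representation and
generic traversal helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: PDB v3 element symbols recognised as hydrogen isotopes.
HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})

#: Covalent radii (Angstrom), single-bond values for elements that occur in
#: protein heavy-atom work.  Used by bond inference with a +0.45 A tolerance.
COVALENT_RADII = {
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "SE": 1.20,
    "P": 1.07,
    "H": 0.31,
    "D": 0.31,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "FE": 1.32,
    "ZN": 1.22,
    "MG": 1.41,
    "CA": 1.76,
    "NA": 1.66,
    "K": 2.03,
    "MN": 1.39,
}


@dataclass
class Atom:
    """A single heavy (or, pre-preparation, hydrogen) atom."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        self.element = self.element.strip().upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in HYDROGEN_ELEMENTS

    def distance_to(self, other: "Atom") -> float:
        return float(math.dist(self.coords, other.coords))


@dataclass
class Residue:
    """A residue identified by (seq_id, insertion_code) within its chain."""

    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} {self.seq_id}{self.insertion_code}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_hetero(self) -> bool:
        return bool(self.atoms) and all(a.is_hetero for a in self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_id: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {seq_id}{insertion_code}")


@dataclass
class StructureModel:
    """Single-model structure; the substrate of every operation in the package."""

    identifier: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.identifier}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for chain in self.chains:
            for residue in chain.residues:
                yield chain, residue

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for residue in chain.residues:
                for atom in residue.atoms:
                    yield chain, residue, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coordinates(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, traversal order."""
        coords = [a.coords for _, _, a in self.iter_atoms()]
        if not coords:
            return np.empty((0, 3))
        return np.vstack(coords)


#: Stable key addressing one atom across reports: (chain, seq_id, icode, atom name).
AtomKey = tuple[str, int, str, str]


def atom_key(chain: Chain, residue: Residue, atom: Atom) -> AtomKey:
    return (chain.chain_id, residue.seq_id, residue.insertion_code, atom.name)
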