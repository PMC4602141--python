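"""Synthetic structures with known ground truth.

Everything the test-suite needs runs offline: idealized residues built
from internal-coordinate templates, extended peptides, and two-chain
"planted" complexes in which selected charged-atom distances are set to
specified values.  The geometry is idealized (extended backbone,
canonical bond lengths/angles, no rotamer sampling or energy
minimization) — the fixtures exercise atom typing and distance
geometry, not conformational realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .geometry import place_atom, rotation_matrix
from .model import Atom, Chain, Residue, StructureModel
from .topology import RESIDUE_TOPOLOGIES, element_of

# Internal-coordinate recipe entries: atom -> (refA, refB, refC, bond, angle, torsion).
# place_atom(A, B, C, ...) sets angle B-C-D and dihedral A-B-C-D.
_Recipe = dict[str, tuple[str, str, str, float, float, float]]

_CHAIN_CB = ("C", "N", "CA", 1.53, 110.5, -122.0)

_SIDE_CHAIN_RECIPES: dict[str, _Recipe] = {
    "GLY": {},
    "ALA": {"CB": _CHAIN_CB},
    "SER": {"CB": _CHAIN_CB, "OG": ("N", "CA", "CB", 1.41, 110.5, 180.0)},
    "CYS": {"CB": _CHAIN_CB, "SG": ("N", "CA", "CB", 1.81, 113.8, 180.0)},
    "THR": {
        "CB": _CHAIN_CB,
        "OG1": ("N", "CA", "CB", 1.41, 109.5, 180.0),
        "CG2": ("N", "CA", "CB", 1.52, 110.5, 60.0),
    },
    "VAL": {
        "CB": _CHAIN_CB,
        "CG1": ("N", "CA", "CB", 1.52, 110.5, 180.0),
        "CG2": ("N", "CA", "CB", 1.52, 110.5, 60.0),
    },
    "LEU": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.53, 116.3, 180.0),
        "CD1": ("CA", "CB", "CG", 1.52, 110.5, 180.0),
        "CD2": ("CA", "CB", "CG", 1.52, 110.5, 60.0),
    },
    "ILE": {
        "CB": _CHAIN_CB,
        "CG1": ("N", "CA", "CB", 1.53, 110.5, 180.0),
        "CG2": ("N", "CA", "CB", 1.53, 110.5, -60.0),
        "CD1": ("CA", "CB", "CG1", 1.52, 113.8, 180.0),
    },
    "MET": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 114.0, 180.0),
        "SD": ("CA", "CB", "CG", 1.81, 112.7, 180.0),
        "CE": ("CB", "CG", "SD", 1.79, 100.9, 180.0),
    },
    "PRO": {
        "CB": ("C", "N", "CA", 1.53, 103.0, -120.0),
        "CG": ("N", "CA", "CB", 1.49, 104.5, -20.0),
        # placed off the backbone N so the pyrrolidine ring closes without
        # colliding with the preceding residue's carbonyl carbon
        "CD": ("C", "CA", "N", 1.47, 112.0, 150.0),
    },
    "PHE": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.50, 113.8, 180.0),
        "CD1": ("CA", "CB", "CG", 1.39, 120.8, 90.0),
        "CD2": ("CD1", "CB", "CG", 1.39, 120.8, 180.0),
        "CE1": ("CB", "CG", "CD1", 1.39, 121.0, 180.0),
        "CE2": ("CB", "CG", "CD2", 1.39, 121.0, 180.0),
        "CZ": ("CG", "CD1", "CE1", 1.39, 120.0, 0.0),
    },
    "TYR": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.51, 113.8, 180.0),
        "CD1": ("CA", "CB", "CG", 1.39, 120.8, 90.0),
        "CD2": ("CD1", "CB", "CG", 1.39, 120.8, 180.0),
        "CE1": ("CB", "CG", "CD1", 1.39, 121.0, 180.0),
        "CE2": ("CB", "CG", "CD2", 1.39, 121.0, 180.0),
        "CZ": ("CG", "CD1", "CE1", 1.39, 120.0, 0.0),
        "OH": ("CD1", "CE1", "CZ", 1.38, 119.9, 180.0),
    },
    "TRP": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.50, 113.8, 180.0),
        "CD1": ("CA", "CB", "CG", 1.37, 126.9, 90.0),
        "CD2": ("CD1", "CB", "CG", 1.43, 126.7, 180.0),
        "NE1": ("CB", "CG", "CD1", 1.38, 110.2, 180.0),
        "CE2": ("CG", "CD1", "NE1", 1.37, 109.0, 0.0),
        "CE3": ("CD1", "CG", "CD2", 1.40, 133.9, 180.0),
        "CZ2": ("CD1", "NE1", "CE2", 1.40, 130.4, 180.0),
        "CZ3": ("CG", "CD2", "CE3", 1.39, 118.8, 180.0),
        "CH2": ("CD2", "CE3", "CZ3", 1.37, 121.2, 0.0),
    },
    "HIS": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.50, 113.8, 180.0),
        "ND1": ("CA", "CB", "CG", 1.38, 122.7, 90.0),
        "CD2": ("ND1", "CB", "CG", 1.36, 131.0, 180.0),
        "CE1": ("CB", "CG", "ND1", 1.32, 109.3, 180.0),
        "NE2": ("CG", "ND1", "CE1", 1.32, 108.4, 0.0),
    },
    "ASP": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 113.0, 180.0),
        "OD1": ("CA", "CB", "CG", 1.25, 118.5, 60.0),
        "OD2": ("CA", "CB", "CG", 1.25, 118.5, -120.0),
    },
    "ASN": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 113.0, 180.0),
        "OD1": ("CA", "CB", "CG", 1.23, 120.8, 60.0),
        "ND2": ("CA", "CB", "CG", 1.33, 116.4, -120.0),
    },
    "GLU": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 114.0, 180.0),
        "CD": ("CA", "CB", "CG", 1.52, 112.6, 180.0),
        "OE1": ("CB", "CG", "CD", 1.25, 118.5, 0.0),
        "OE2": ("CB", "CG", "CD", 1.25, 118.5, 180.0),
    },
    "GLN": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 114.0, 180.0),
        "CD": ("CA", "CB", "CG", 1.52, 112.6, 180.0),
        "OE1": ("CB", "CG", "CD", 1.23, 120.8, 0.0),
        "NE2": ("CB", "CG", "CD", 1.33, 116.4, 180.0),
    },
    "LYS": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 114.0, 180.0),
        "CD": ("CA", "CB", "CG", 1.52, 111.3, 180.0),
        "CE": ("CB", "CG", "CD", 1.52, 111.3, 180.0),
        "NZ": ("CG", "CD", "CE", 1.49, 111.9, 180.0),
    },
    "ARG": {
        "CB": _CHAIN_CB,
        "CG": ("N", "CA", "CB", 1.52, 114.0, 180.0),
        "CD": ("CA", "CB", "CG", 1.52, 111.3, 180.0),
        "NE": ("CB", "CG", "CD", 1.46, 112.0, 180.0),
        "CZ": ("CG", "CD", "NE", 1.33, 124.2, 180.0),
        "NH1": ("CD", "NE", "CZ", 1.33, 120.0, 0.0),
        "NH2": ("CD", "NE", "CZ", 1.33, 120.0, 180.0),
    },
}

#: Backbone phi used for proline residues (deg); the pyrrolidine ring
#: excludes the extended value every other residue gets.
PROLINE_PHI = -65.0

# Backbone internal coordinates (trans peptide, extended phi/psi = 180).
_PEPTIDE = {
    "N": (1.33, 116.2, 180.0),   # from previous C; psi torsion
    "CA": (1.458, 121.7, 180.0),  # omega
    "C": (1.525, 111.2, 180.0),   # phi
    "O": (1.231, 120.5, 0.0),     # N-CA-C-O, anti to the next N
    "OXT": (1.25, 117.0, 180.0),
}


@dataclass(frozen=True)
class ResidueTemplate:
    """One standard residue: topology plus internal-coordinate recipe."""

    residue_code: str
    atoms: tuple[str, ...]
    elements: dict[str, str] = field(hash=False)
    bonds: frozenset[frozenset[str]] = field(hash=False)
    recipe: _Recipe = field(hash=False)


def residue_template(code: str) -> ResidueTemplate:
    if code not in RESIDUE_TOPOLOGIES:
        raise KeyError(f"no template for residue code {code!r}")
    topo = RESIDUE_TOPOLOGIES[code]
    return ResidueTemplate(
        residue_code=code,
        atoms=topo.atoms,
        elements=dict(topo.elements),
        bonds=topo.bonds,
        recipe=_SIDE_CHAIN_RECIPES[code],
    )


def _seed_backbone() -> dict[str, np.ndarray]:
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_atom(np.array([0.0, -1.0, 0.0]), n, ca, 1.525, 111.2, 0.0)
    return {"N": n, "CA": ca, "C": c}


def _place_side_chain(code: str, pos: dict[str, np.ndarray]) -> None:
    for atom, (ra, rb, rc, bond, angle, torsion) in _SIDE_CHAIN_RECIPES[code].items():
        pos[atom] = place_atom(pos[ra], pos[rb], pos[rc], bond, angle, torsion)


def build_residue(code: str, seq_id: int = 1, serial_start: int = 1) -> Residue:
    """Realize one residue template in 3-D (no OXT; see build_peptide)."""
    template = residue_template(code)  # raises KeyError for unknown codes
    pos = _seed_backbone()
    bond, angle, torsion = _PEPTIDE["O"]
    pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"], bond, angle, torsion)
    _place_side_chain(code, pos)
    residue = Residue(name=code, seq_id=seq_id)
    serial = serial_start
    for name in template.atoms:
        residue.atoms.append(
            Atom(serial=serial, name=name, element=template.elements[name], coords=pos[name])
        )
        serial += 1
    return residue


def build_peptide(
    sequence: list[str] | tuple[str, ...] | str,
    conformation: str = "extended",
    chain_id: str = "A",
    serial_start: int = 1,
) -> Chain:
    """Extended peptide chain; consecutive residues trans-peptide bonded.

    ``sequence`` is a list of 3-letter codes.  The last residue gets an
    OXT.  Residues are numbered from 1.
    """
    if isinstance(sequence, str):
        sequence = [sequence]
    if not sequence:
        raise ValueError("empty sequence")
    if conformation != "extended":
        raise ValueError(f"unsupported conformation {conformation!r}")
    for code in sequence:
        if code not in RESIDUE_TOPOLOGIES:
            raise KeyError(f"no template for residue code {code!r}")

    chain = Chain(chain_id=chain_id)
    serial = serial_start
    prev: dict[str, np.ndarray] | None = None
    for i, code in enumerate(sequence):
        if prev is None:
            pos = _seed_backbone()
        else:
            pos = {}
            b, a, t = _PEPTIDE["N"]
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"], b, a, t)
            b, a, t = _PEPTIDE["CA"]
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"], b, a, t)
            b, a, t = _PEPTIDE["C"]
            # proline cannot adopt phi ~ 180; use its canonical phi instead
            phi = PROLINE_PHI if code == "PRO" else t
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"], b, a, phi)
        b, a, t = _PEPTIDE["O"]
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"], b, a, t)
        _place_side_chain(code, pos)

        template = residue_template(code)
        names = list(template.atoms)
        if i == len(sequence) - 1:
            b, a, t = _PEPTIDE["OXT"]
            pos["OXT"] = place_atom(pos["N"], pos["CA"], pos["C"], b, a, t)
            names.append("OXT")
        residue = Residue(name=code, seq_id=i + 1)
        for name in names:
            element = template.elements.get(name, element_of(name))
            residue.atoms.append(
                Atom(serial=serial, name=name, element=element, coords=pos[name])
            )
            serial += 1
        chain.residues.append(residue)
        prev = pos
    return chain


def build_all_residue_peptide(chain_id: str = "A") -> Chain:
    """A 20-mer containing each standard residue exactly once (alphabetical)."""
    return build_peptide(sorted(RESIDUE_TOPOLOGIES), chain_id=chain_id)


@dataclass(frozen=True)
class PlantedContact:
    """One planted inter-chain atom-pair distance."""

    residue_a: int  # seq id in chain A
    atom_a: str
    residue_b: int  # seq id in chain B
    atom_b: str
    distance: float  # Angstrom


@dataclass(frozen=True)
class PlantedDimerSpec:
    sequence_a: tuple[str, ...]
    sequence_b: tuple[str, ...]
    contacts: tuple[PlantedContact, ...]
    seed: int = 0
    identifier: str = "planted-dimer"


#: Planted distances must be achieved at least this closely (Angstrom).
PLANT_TOLERANCE = 0.05
#: No two atoms of different chains may come closer than this, except
#: atoms of residues involved in a planted contact.
CLASH_LIMIT = 2.0


def build_planted_dimer(spec: PlantedDimerSpec) -> StructureModel:
    """Two extended chains posed so every planted distance is met.

    Chain B is rigid-body docked onto chain A by least squares over the
    planted contacts, with a soft repulsion term keeping the remaining
    atoms apart, from a seeded set of starting orientations.  Raises if
    no pose satisfies every contact to within ``PLANT_TOLERANCE``.
    """
    chain_a = build_peptide(list(spec.sequence_a), chain_id="A")
    chain_b = build_peptide(list(spec.sequence_b), chain_id="B", serial_start=1000)

    a_coords = np.vstack([a.coords for r in chain_a.residues for a in r.atoms])
    b_coords = np.vstack([a.coords for r in chain_b.residues for a in r.atoms])

    pa = np.vstack(
        [chain_a.residue(c.residue_a).atom(c.atom_a).coords for c in spec.contacts]
    )
    b_idx = []
    flat_b = [(r.seq_id, a.name) for r in chain_b.residues for a in r.atoms]
    for c in spec.contacts:
        b_idx.append(flat_b.index((c.residue_b, c.atom_b)))
    b_idx = np.array(b_idx, dtype=int)
    targets = np.array([c.distance for c in spec.contacts])

    # atoms whose burial is *not* intended: everything except the side
    # chains of the contact residues (their backbones should stay apart)
    backbone = {"N", "CA", "C", "O", "OXT"}
    contact_res_a = {c.residue_a for c in spec.contacts}
    contact_res_b = {c.residue_b for c in spec.contacts}
    flat_a = [(r.seq_id, a.name) for r in chain_a.residues for a in r.atoms]
    free_a = np.array(
        [i for i, (r, name) in enumerate(flat_a)
         if r not in contact_res_a or name in backbone],
        dtype=int,
    )
    free_b = np.array(
        [i for i, (r, name) in enumerate(flat_b)
         if r not in contact_res_b or name in backbone],
        dtype=int,
    )

    centroid_b = b_coords.mean(axis=0)

    def transform(params: np.ndarray, coords: np.ndarray) -> np.ndarray:
        rx, ry, rz, tx, ty, tz = params
        rot = (
            rotation_matrix([1, 0, 0], rx)
            @ rotation_matrix([0, 1, 0], ry)
            @ rotation_matrix([0, 0, 1], rz)
        )
        return (coords - centroid_b) @ rot.T + centroid_b + np.array([tx, ty, tz])

    def residuals(params: np.ndarray) -> np.ndarray:
        moved = transform(params, b_coords)
        dist = np.linalg.norm(moved[b_idx] - pa, axis=1)
        res = list(dist - targets)
        # soft repulsion between non-contact atoms of the two chains
        if len(free_a) and len(free_b):
            d = cdist(a_coords[free_a], moved[free_b])
            close = np.minimum(d - (CLASH_LIMIT + 1.0), 0.0)
            res.append(0.3 * np.linalg.norm(close))
        return np.array(res)

    rng = np.random.default_rng(spec.seed)
    # among all poses satisfying the planted distances, keep the one whose
    # non-contact atoms are farthest apart: only the planted contact touches
    best = None
    best_gap = -np.inf
    for attempt in range(24):
        angles = rng.uniform(-180, 180, size=3)
        offset_dir = rng.normal(size=3)
        offset_dir /= np.linalg.norm(offset_dir)
        x0 = np.concatenate([angles, pa.mean(axis=0) + 8.0 * offset_dir - centroid_b])
        sol = least_squares(residuals, x0, method="trf", max_nfev=4000)
        moved = transform(sol.x, b_coords)
        dist = np.linalg.norm(moved[b_idx] - pa, axis=1)
        if np.all(np.abs(dist - targets) <= PLANT_TOLERANCE):
            min_gap = (
                cdist(a_coords[free_a], moved[free_b]).min()
                if len(free_a) and len(free_b)
                else np.inf
            )
            if min_gap >= CLASH_LIMIT and min_gap > best_gap:
                best = moved
                best_gap = min_gap
    if best is None:
        raise ValueError(
            f"cannot satisfy planted contacts {spec.contacts} with rigid chains; "
            "spec is geometrically unsatisfiable"
        )

    k = 0
    for residue in chain_b.residues:
        for atom in residue.atoms:
            atom.coords = best[k]
            k += 1
    return StructureModel(identifier=spec.identifier, chains=[chain_a, chain_b])


def simple_salt_bridge_dimer(distance: float = 3.5, seed: int = 0) -> StructureModel:
    """GLY-LYS-GLY / GLY-ASP-GLY dimer with one planted NZ–OD1 contact."""
    spec = PlantedDimerSpec(
        sequence_a=("GLY", "LYS", "GLY"),
        sequence_b=("GLY", "ASP", "GLY"),
        contacts=(PlantedContact(2, "NZ", 2, "OD1", distance),),
        seed=seed,
        identifier=f"salt-bridge-{distance:.2f}",
    )
    return build_planted_dimer(spec)
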