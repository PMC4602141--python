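"""Interface analysis between chain groups.

Three related views of a complex interface:

* **salt bridges** — inter-group charged pairs: a Lys/Arg side-chain
  nitrogen within a cutoff (default 4.0 A, a standard literature
  convention) of an Asp/Glu carboxylate oxygen.  Counted per residue
  pair, reporting the minimal-distance atom pair, so NH1/NH2 or
  OD1/OD2 ambiguity never double-counts.  Histidine is treated as
  uncharged and never participates.
* **interface atoms** — atoms that lose accessible area on complex
  formation (delta-SASA), or that have an opposite-group atom within a
  distance cutoff.
* **per-class buried area** — the buried area of each side partitioned
  over the four atom classes, quantifying how hydrophobic or charged
  an interface is.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from scipy.spatial import cKDTree

from .classify import AtomClass, ClassifiedStructure, NEGATIVE_ATOMS, POSITIVE_ATOMS
from .model import AtomKey, Chain, StructureModel
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, SasaResult, shrake_rupley_sasa

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0
DEFAULT_CONTACT_CUTOFF = 5.0


@dataclass(frozen=True)
class SaltBridge:
    """One inter-group charged pair, reported at residue level."""

    cation_chain: str
    cation_seq: int
    cation_icode: str
    cation_resname: str
    cation_atom: str
    anion_chain: str
    anion_seq: int
    anion_icode: str
    anion_resname: str
    anion_atom: str
    distance: float

    @property
    def residue_pair(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (
            (self.cation_chain, self.cation_seq, self.cation_icode),
            (self.anion_chain, self.anion_seq, self.anion_icode),
        )

    def label(self) -> str:
        one = {"LYS": "K", "ARG": "R", "ASP": "D", "GLU": "E"}
        c = one.get(self.cation_resname, self.cation_resname)
        a = one.get(self.anion_resname, self.anion_resname)
        return (
            f"{c}{self.cation_seq}{self.cation_icode}({self.cation_chain})-"
            f"{a}{self.anion_seq}{self.anion_icode}({self.anion_chain})"
        )


def _validate_groups(
    model: StructureModel, group_a: set[str], group_b: set[str]
) -> None:
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    overlap = group_a & group_b
    if overlap:
        raise ValueError(f"chain groups overlap: {sorted(overlap)}")
    present = set(model.chain_ids())
    unknown = (group_a | group_b) - present
    if unknown:
        raise ValueError(
            f"unknown chain id(s) {sorted(unknown)}; model has {sorted(present)}"
        )


def _charged_atoms(
    model: StructureModel, chains: set[str], charged: frozenset[tuple[str, str]]
) -> tuple[list[tuple[str, int, str, str, str]], np.ndarray]:
    info: list[tuple[str, int, str, str, str]] = []
    coords: list[np.ndarray] = []
    for chain in model.chains:
        if chain.chain_id not in chains:
            continue
        for residue in chain.residues:
            for atom in residue.atoms:
                if (residue.name, atom.name) in charged:
                    info.append(
                        (chain.chain_id, residue.seq_id, residue.insertion_code,
                         residue.name, atom.name)
                    )
                    coords.append(atom.coords)
    return info, (np.vstack(coords) if coords else np.empty((0, 3)))


def find_salt_bridges(
    model: StructureModel,
    group_a: set[str] | frozenset[str],
    group_b: set[str] | frozenset[str],
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> list[SaltBridge]:
    """Inter-group charged pairs within ``cutoff``; one bridge per residue pair.

    Symmetric in the two groups; the cation may sit in either.  Sorted
    by (cation chain, residue, anion chain, residue) for stable output.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    group_a, group_b = set(group_a), set(group_b)
    _validate_groups(model, group_a, group_b)

    bridges: dict[tuple, SaltBridge] = {}
    for cat_chains, an_chains in ((group_a, group_b), (group_b, group_a)):
        cat_info, cat_xyz = _charged_atoms(model, cat_chains, POSITIVE_ATOMS)
        an_info, an_xyz = _charged_atoms(model, an_chains, NEGATIVE_ATOMS)
        if not len(cat_info) or not len(an_info):
            continue
        tree = cKDTree(an_xyz)
        for i, cat in enumerate(cat_info):
            for j in tree.query_ball_point(cat_xyz[i], cutoff):
                an = an_info[j]
                d = float(np.linalg.norm(cat_xyz[i] - an_xyz[j]))
                pair_key = (cat[:3], an[:3])
                prev = bridges.get(pair_key)
                if prev is None or d < prev.distance:
                    bridges[pair_key] = SaltBridge(
                        cation_chain=cat[0], cation_seq=cat[1], cation_icode=cat[2],
                        cation_resname=cat[3], cation_atom=cat[4],
                        anion_chain=an[0], anion_seq=an[1], anion_icode=an[2],
                        anion_resname=an[3], anion_atom=an[4],
                        distance=d,
                    )
    return sorted(
        bridges.values(),
        key=lambda b: (b.cation_chain, b.cation_seq, b.cation_icode,
                       b.anion_chain, b.anion_seq, b.anion_icode),
    )


@dataclass
class InterfaceReport:
    """Interface atoms, buried areas and salt bridges for one chain-group split."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    method: str
    interface_atoms_a: list[AtomKey] = field(default_factory=list)
    interface_atoms_b: list[AtomKey] = field(default_factory=list)
    buried_area_a: float = 0.0
    buried_area_b: float = 0.0
    #: per-atom SASA lost on complex formation (positive deltas only)
    delta_sasa_a: dict[AtomKey, float] = field(default_factory=dict)
    delta_sasa_b: dict[AtomKey, float] = field(default_factory=dict)
    salt_bridges: list[SaltBridge] = field(default_factory=list)

    def to_json(self) -> str:
        def keyfmt(k: AtomKey) -> str:
            return f"{k[0]}/{k[1]}{k[2]}/{k[3]}"

        payload = {
            "group_a": list(self.group_a),
            "group_b": list(self.group_b),
            "method": self.method,
            "buried_area_a": round(self.buried_area_a, 3),
            "buried_area_b": round(self.buried_area_b, 3),
            "interface_atoms_a": [keyfmt(k) for k in self.interface_atoms_a],
            "interface_atoms_b": [keyfmt(k) for k in self.interface_atoms_b],
            "salt_bridges": [
                {
                    "cation": f"{b.cation_resname} {b.cation_chain}"
                              f"{b.cation_seq}{b.cation_icode} {b.cation_atom}",
                    "anion": f"{b.anion_resname} {b.anion_chain}"
                             f"{b.anion_seq}{b.anion_icode} {b.anion_atom}",
                    "label": b.label(),
                    "distance": round(b.distance, 3),
                }
                for b in self.salt_bridges
            ],
        }
        return json.dumps(payload, indent=2)


def _submodel(model: StructureModel, chains: set[str]) -> StructureModel:
    return StructureModel(
        identifier=model.identifier,
        chains=[c for c in model.chains if c.chain_id in chains],
        source_format=model.source_format,
    )


def interface_atoms(
    model: StructureModel,
    group_a: set[str] | frozenset[str],
    group_b: set[str] | frozenset[str],
    method: str = "delta-sasa",
    distance_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    n_points: int = DEFAULT_N_POINTS,
    probe: float = DEFAULT_PROBE,
) -> InterfaceReport:
    """Interface atoms and buried area between two chain groups.

    ``method="delta-sasa"`` marks an atom interfacial when its
    accessible area in the isolated group exceeds its area in the
    complex; ``method="distance"`` when any opposite-group atom lies
    within ``distance_cutoff``.  Buried areas are always the summed
    positive SASA deltas per side, so the partition invariant holds for
    either method.
    """
    if method not in ("delta-sasa", "distance"):
        raise ValueError(f"unknown method {method!r}")
    group_a, group_b = set(group_a), set(group_b)
    _validate_groups(model, group_a, group_b)

    both = _submodel(model, group_a | group_b)
    sasa_complex = shrake_rupley_sasa(both, probe=probe, n_points=n_points)
    report = InterfaceReport(
        group_a=tuple(sorted(group_a)),
        group_b=tuple(sorted(group_b)),
        method=method,
    )
    for side, chains in (("a", group_a), ("b", group_b)):
        alone = shrake_rupley_sasa(
            _submodel(model, chains), probe=probe, n_points=n_points
        )
        deltas = {
            key: alone.areas[key] - sasa_complex.areas[key]
            for key in alone.areas
            if alone.areas[key] - sasa_complex.areas[key] > 1e-9
        }
        setattr(report, f"delta_sasa_{side}", deltas)
        setattr(report, f"buried_area_{side}", float(sum(deltas.values())))

    if method == "delta-sasa":
        report.interface_atoms_a = sorted(report.delta_sasa_a)
        report.interface_atoms_b = sorted(report.delta_sasa_b)
    else:
        report.interface_atoms_a, report.interface_atoms_b = _contact_atoms(
            model, group_a, group_b, distance_cutoff
        )

    report.salt_bridges = find_salt_bridges(
        model, group_a, group_b, cutoff=salt_bridge_cutoff
    )
    return report


def _contact_atoms(
    model: StructureModel, group_a: set[str], group_b: set[str], cutoff: float
) -> tuple[list[AtomKey], list[AtomKey]]:
    from .model import atom_key

    keys_a, xyz_a, keys_b, xyz_b = [], [], [], []
    for chain, residue, atom in model.iter_atoms():
        if chain.chain_id in group_a:
            keys_a.append(atom_key(chain, residue, atom))
            xyz_a.append(atom.coords)
        elif chain.chain_id in group_b:
            keys_b.append(atom_key(chain, residue, atom))
            xyz_b.append(atom.coords)
    if not keys_a or not keys_b:
        return [], []
    tree_b = cKDTree(np.vstack(xyz_b))
    pairs = tree_b.query_ball_point(np.vstack(xyz_a), cutoff)
    hit_a = sorted(keys_a[i] for i, js in enumerate(pairs) if js)
    hit_b = sorted({keys_b[j] for js in pairs for j in js})
    return hit_a, hit_b


#: Marker used instead of NaN arithmetic when an interface buries no area.
UNDEFINED = "undefined"


def interface_class_profile(
    classified: ClassifiedStructure, report: InterfaceReport
) -> dict[str, dict[str, dict[str, float | str]]]:
    """Per-side buried area and fraction per atom class.

    Returns ``{"a": {class: {"area": A2, "fraction": f}}, "b": ...}``;
    fractions are the string marker ``"undefined"`` when a side buries
    no area at all.
    """
    out: dict[str, dict[str, dict[str, float | str]]] = {}
    for side in ("a", "b"):
        deltas: dict[AtomKey, float] = getattr(report, f"delta_sasa_{side}")
        per_class = {cls: 0.0 for cls in AtomClass}
        for key, area in deltas.items():
            per_class[classified.classes[key]] += area
        total = sum(per_class.values())
        out[side] = {
            str(cls): {
                "area": per_class[cls],
                "fraction": (per_class[cls] / total) if total > 0 else UNDEFINED,
            }
            for cls in AtomClass
        }
    return out


def salt_bridges_tsv(bridges: list[SaltBridge]) -> str:
    buf = StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow([
        "cation_chain", "cation_resid", "cation_icode", "cation_resname", "cation_atom",
        "anion_chain", "anion_resid", "anion_icode", "anion_resname", "anion_atom",
        "distance", "label",
    ])
    for b in bridges:
        w.writerow([
            b.cation_chain, b.cation_seq, b.cation_icode, b.cation_resname, b.cation_atom,
            b.anion_chain, b.anion_seq, b.anion_icode, b.anion_resname, b.anion_atom,
            f"{b.distance:.3f}", b.label(),
        ])
    return buf.getvalue()


def salt_bridges_pymol(bridges: list[SaltBridge], object_name: str = "bridges") -> str:
    """PyMOL distance objects for visual inspection of detected bridges."""
    lines = []
    for i, b in enumerate(bridges, start=1):
        sel_c = f"(chain {b.cation_chain} and resi {b.cation_seq}{b.cation_icode} and name {b.cation_atom})"
        sel_a = f"(chain {b.anion_chain} and resi {b.anion_seq}{b.anion_icode} and name {b.anion_atom})"
        lines.append(f"distance {object_name}_{i}, {sel_c}, {sel_a}")
    lines.append(f"group {object_name}, {object_name}_*")
    return "\n".join(lines) + "\n"
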