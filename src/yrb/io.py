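"""Reading PDB/mmCIF into the structure model, and writing PDB back out.

gemmi does the heavy lifting for both formats (including transparent
.gz); this module reduces its output to the package's single-model,
altloc-resolved representation and handles the reverse conversion for
PDB output with optional B-factor overrides.
"""

from __future__ import annotations

import os
from typing import Mapping

import gemmi
import numpy as np

from .model import Atom, AtomKey, Chain, Residue, StructureModel

_FORMATS = ("pdb", "mmcif", "auto")


class StructureParseError(ValueError):
    """Input file unreadable or empty of atoms."""


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    return {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[fmt]


def infer_element(atom_name: str) -> str:
    """Element from a PDB v3 atom name when the element column is absent.

    The convention right-justifies the element in the first two name
    columns; hydrogen names may carry a leading digit ("1HG1", "2HB").
    Two-letter elements relevant for proteins (SE, FE, ZN, ...) only
    occur in names that start with those letters and a following
    non-digit position, which for protein heavy atoms reduces to: strip
    digits, first letter is the element — except SE/CL/BR/FE/ZN/MG/NA
    names that fill both columns.
    """
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        return "H"
    two = name[:2].upper()
    if two in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return two
    return name[0].upper()


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a structure file into a clean single-model representation.

    Keeps the first coordinate model only, resolves altlocs to the
    highest-occupancy variant (ties broken by file order) and fills in
    missing element symbols from atom names.  Hydrogens are retained;
    call :func:`strip_hydrogens` to drop them.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(path, format=_coor_format(format))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path!r}: {exc}") from exc

    identifier = st.name.lower() if st.name else os.path.splitext(os.path.basename(path))[0]
    source = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    model = StructureModel(identifier=identifier, source_format=source)
    if len(st) == 0:
        raise StructureParseError(f"{path!r}: no coordinate model")

    first = st[0]
    serial = 0
    for g_chain in first:
        chain = Chain(chain_id=g_chain.name)
        for g_res in g_chain:
            residue = Residue(
                name=g_res.name.strip().upper(),
                seq_id=g_res.seqid.num,
                insertion_code=(g_res.seqid.icode or "").strip(),
            )
            for g_atom in _resolve_altlocs(g_res):
                serial += 1
                element = g_atom.element.name.upper() if not g_atom.element.is_metal else g_atom.element.name.upper()
                if not element or element == "X":
                    element = infer_element(g_atom.name)
                altloc = g_atom.altloc if g_atom.altloc not in ("\x00", "") else ""
                residue.atoms.append(
                    Atom(
                        serial=serial,
                        name=g_atom.name.strip(),
                        element=element,
                        coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                        alt_loc=altloc,
                        occupancy=min(max(g_atom.occ, 0.0), 1.0),
                        b_factor=g_atom.b_iso,
                        is_hetero=(g_res.het_flag == "H"),
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            model.chains.append(chain)

    if model.n_atoms == 0:
        raise StructureParseError(f"{path!r}: structure contains no atoms")
    return model


def _resolve_altlocs(g_res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: blank altloc wins, else highest occupancy, ties by file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in g_res:
        name = atom.name.strip()
        if name not in best:
            best[name] = atom
            order.append(name)
            continue
        kept = best[name]
        kept_blank = kept.altloc in ("\x00", "")
        if kept_blank:
            continue
        if atom.altloc in ("\x00", "") or atom.occ > kept.occ:
            best[name] = atom
    return [best[name] for name in order]


def strip_hydrogens(model: StructureModel) -> StructureModel:
    """Remove all hydrogen/deuterium atoms in place; idempotent."""
    for chain in model.chains:
        for residue in chain.residues:
            residue.atoms = [a for a in residue.atoms if not a.is_hydrogen]
        chain.residues = [r for r in chain.residues if r.atoms]
    model.chains = [c for c in model.chains if c.residues]
    return model


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    """Convert back to a gemmi Structure (single model)."""
    st = gemmi.Structure()
    st.name = model.identifier
    g_model = gemmi.Model(1)
    for chain in model.chains:
        g_chain = gemmi.Chain(chain.chain_id)
        for residue in chain.residues:
            g_res = gemmi.Residue()
            g_res.name = residue.name
            g_res.seqid = gemmi.SeqId(residue.seq_id, residue.insertion_code or " ")
            g_res.het_flag = "H" if residue.is_hetero else "A"
            for atom in residue.atoms:
                g_atom = gemmi.Atom()
                g_atom.name = atom.name
                g_atom.element = gemmi.Element(atom.element.capitalize())
                g_atom.pos = gemmi.Position(*atom.coords)
                g_atom.occ = atom.occupancy
                g_atom.b_iso = atom.b_factor
                if atom.alt_loc:
                    g_atom.altloc = atom.alt_loc
                g_res.add_atom(g_atom)
            g_chain.add_residue(g_res)
        g_model.add_chain(g_chain)
    st.add_model(g_model)
    st.setup_entities()
    return st


def write_pdb(
    model: StructureModel,
    path: str | os.PathLike,
    b_factor_override: Mapping[AtomKey, float] | None = None,
) -> None:
    """Write the model as fixed-column PDB, optionally overriding B-factors.

    Coordinates round-trip to 3 decimals and B-factors to 2, per the
    format.  Chain ids longer than the single column the PDB format
    allows raise instead of being truncated.
    """
    for chain in model.chains:
        if len(chain.chain_id) > 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} does not fit the one-column PDB "
                "chain field; rename the chain or write mmCIF"
            )
    if b_factor_override:
        known = {
            (c.chain_id, r.seq_id, r.insertion_code, a.name)
            for c, r, a in model.iter_atoms()
        }
        unknown = set(b_factor_override) - known
        if unknown:
            raise KeyError(f"b_factor_override keys not in model: {sorted(unknown)[:5]}")

    st = to_gemmi(model)
    if b_factor_override:
        for g_chain in st[0]:
            for g_res in g_chain:
                for g_atom in g_res:
                    key = (
                        g_chain.name,
                        g_res.seqid.num,
                        (g_res.seqid.icode or "").strip(),
                        g_atom.name.strip(),
                    )
                    if key in b_factor_override:
                        g_atom.b_iso = float(b_factor_override[key])
    st.write_pdb(os.fspath(path))
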