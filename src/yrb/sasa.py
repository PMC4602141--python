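"""Shrake–Rupley solvent-accessible surface area.

Each atom's van der Waals sphere is inflated by the probe radius
(water, 1.4 A) and covered with a deterministic golden-spiral point
set; the accessible area is the fraction of points not buried inside
any neighbouring atom's inflated sphere.  No randomness is involved,
so areas are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomKey, StructureModel, atom_key

#: Van der Waals radii (Angstrom) keyed by element, a standard protein set.
VDW_RADII_PROTOR = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "MN": 1.97,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points via the golden-angle spiral."""
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom accessible areas (Angstrom^2) plus the run parameters."""

    areas: dict[AtomKey, float]
    probe_radius: float
    n_sphere_points: int
    radii_set_name: str = "protor"

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    def atom_area(self, key: AtomKey) -> float:
        return self.areas[key]


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Per-atom SASA of (typically hydrogen-free) ``model``.

    ``radii`` overrides the element->radius table; atoms whose element
    has no radius raise rather than silently defaulting.
    """
    table = dict(VDW_RADII_PROTOR)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})

    keys: list[AtomKey] = []
    coords: list[np.ndarray] = []
    radii_arr: list[float] = []
    for chain, residue, atom in model.iter_atoms():
        r = table.get(atom.element)
        if r is None:
            raise ValueError(
                f"no van der Waals radius for atom {atom.name!r} "
                f"({chain.chain_id}/{residue.name} {residue.seq_id}, "
                f"element {atom.element!r}); pass a radius override"
            )
        keys.append(atom_key(chain, residue, atom))
        coords.append(atom.coords)
        radii_arr.append(r)

    if not keys:
        return SasaResult({}, probe, n_points)

    xyz = np.vstack(coords)
    rad = np.asarray(radii_arr) + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()

    areas: dict[AtomKey, float] = {}
    for i, key in enumerate(keys):
        pts = xyz[i] + rad[i] * sphere
        neighbor_idx = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 > rad[j] ** 2
        frac = accessible.sum() / n_points
        areas[key] = float(4.0 * np.pi * rad[i] ** 2 * frac)
    return SasaResult(areas, probe, n_points)
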