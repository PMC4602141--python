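"""Small internal-coordinate geometry helpers (NeRF atom placement)."""

from __future__ import annotations

import numpy as np


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Position atom D given references A, B, C (natural extension reference frame).

    ``bond`` is |C-D| in Angstrom, ``angle`` the B-C-D angle and
    ``torsion`` the A-B-C-D dihedral, both in degrees.
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` (normalised internally)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
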