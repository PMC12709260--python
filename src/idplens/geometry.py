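"""Internal-coordinate geometry: NeRF atom placement and dihedral angles."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, bond |CD|, angle B-C-D, dihedral A-B-C-D.

    Natural extension reference frame (NeRF) construction; angles in degrees.
    """
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def dihedrals_vectorized(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Dihedrals (degrees) for many frames at once.

    coords: (n_frames, n_atoms, 3); quads: (n_dihedrals, 4) atom indices.
    Returns (n_frames, n_dihedrals).
    """
    p = coords[:, quads]                       # (F, D, 4, 3)
    b0 = p[:, :, 0] - p[:, :, 1]
    b1 = p[:, :, 2] - p[:, :, 1]
    b2 = p[:, :, 3] - p[:, :, 2]
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
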