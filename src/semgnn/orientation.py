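"""Standardization of molecular orientation.

Encodings of the steric and electronic environment are computed in
Cartesian space, so they would depend on the arbitrary input frame unless
every molecule is first brought into a canonical pose.  The canonical pose
is fixed by three key points: the mass-weighted center of gravity (moved to
the origin), the atom closest to it (atom1, rotated onto the +z axis) and
the atom furthest from it (atom2, rotated into the yz plane with y >= 0).
Both rotations are proper (det = +1), so mirror images remain distinct —
a requirement for modelling enantioselectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Molecule3D

_TIE_TOL = 1e-6
_AXIS_TOL = 1e-10


@dataclass(frozen=True)
class StandardFrame:
    """Rigid motion x -> rotation @ x + translation producing the pose."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    atom1_index: int
    atom2_index: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def center_of_gravity(mol: Molecule3D) -> np.ndarray:
    """Mass-weighted mean position (standard atomic masses), Angstrom."""
    m = mol.masses
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


def _pick_extreme(dist: np.ndarray, mode: str) -> int:
    """Index of the nearest/furthest atom; ties broken by lowest index."""
    best = dist.min() if mode == "near" else dist.max()
    candidates = np.flatnonzero(np.abs(dist - best) <= _TIE_TOL)
    return int(candidates[0])


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking direction v onto +z (identity if degenerate)."""
    norm = np.linalg.norm(v)
    if norm < _AXIS_TOL:
        return np.eye(3)
    u = v / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < _AXIS_TOL:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    angle = np.arctan2(s, c)
    return _axis_angle(axis, angle)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def standardize_orientation(mol: Molecule3D) -> tuple[Molecule3D, StandardFrame]:
    """Bring a molecule into the canonical key-atom pose.

    Returns the posed molecule and the :class:`StandardFrame` that maps the
    source coordinates onto it.  Degenerate cases (single atom, key atom at
    the center, linear molecule) reduce gracefully: undefined rotations are
    skipped, never raised.
    """
    cog = center_of_gravity(mol)
    centered = mol.coords - cog
    dist = np.linalg.norm(centered, axis=1)
    i1 = _pick_extreme(dist, "near")
    i2 = _pick_extreme(dist, "far")

    # step 2: atom1 -> +z
    r1 = _rotation_onto_z(centered[i1])
    rot1 = centered @ r1.T

    # step 3: azimuthal rotation about z putting atom2 in the yz plane, y >= 0
    x2, y2 = rot1[i2, 0], rot1[i2, 1]
    if np.hypot(x2, y2) < _AXIS_TOL:
        rz = np.eye(3)
    else:
        # rotate so that (x2, y2) -> (0, +hypot)
        angle = np.pi / 2 - np.arctan2(y2, x2)
        rz = _axis_angle(np.array([0.0, 0.0, 1.0]), angle)
    rotation = rz @ r1
    posed = centered @ rotation.T
    frame = StandardFrame(rotation, -rotation @ cog, i1, i2)
    return mol.with_coords(posed), frame
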