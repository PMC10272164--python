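"""Per-atom spherical-projection steric maps.

For every atom, a reference sphere (default radius 10 A) is centered on the
atom and rays are cast along an equirectangular angular grid: the polar
angle theta in (0, pi) split into N bins and the azimuth phi in (0, 2 pi)
split into 2N bins, sampled at bin centers.  Each grid entry records the
distance between the molecular van der Waals surface and the reference
sphere along that ray, i.e. ``radius - extent`` where ``extent`` is the
farthest ray/vdW-sphere intersection over all atoms.  Bulky environments
thus show up as small entries on the side they occupy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chemio import Molecule3D
from .constants import BONDI_VDW_RADII
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("semgnn.steric")


@dataclass
class StericConfig:
    """Sphere radius (A), polar grid size N and the vdW radii table."""

    radius: float = 10.0
    n_polar: int = 10
    radii_table: dict[str, float] = field(
        default_factory=lambda: dict(BONDI_VDW_RADII)
    )

    def __post_init__(self) -> None:
        if self.n_polar < 2:
            raise ConfigurationError("n_polar must be >= 2")
        if self.radius <= max(self.radii_table.values()):
            raise ConfigurationError(
                "sphere radius must exceed every vdW radius in the table"
            )

    def vdw_radius(self, symbol: str) -> float:
        try:
            return self.radii_table[symbol]
        except KeyError as exc:
            raise ConfigurationError(
                f"no van der Waals radius for element {symbol!r}"
            ) from exc


@dataclass
class StericMatrix:
    """N x 2N equirectangular map of vdW-surface-to-sphere distances (A)."""

    values: np.ndarray
    center_atom: int


def grid_directions(n_polar: int) -> np.ndarray:
    """Unit ray directions at bin centers, shape (N, 2N, 3).

    theta_i = (i + 1/2) pi / N from the +z pole, phi_j = (j + 1/2) pi / N.
    Bin centers avoid the degenerate poles and the phi = 0 = 2 pi seam.
    """
    n = n_polar
    theta = (np.arange(n) + 0.5) * np.pi / n
    phi = (np.arange(2 * n) + 0.5) * np.pi / n
    st, ct = np.sin(theta), np.cos(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    d = np.empty((n, 2 * n, 3))
    d[..., 0] = st[:, None] * cp[None, :]
    d[..., 1] = st[:, None] * sp[None, :]
    d[..., 2] = ct[:, None] * np.ones_like(phi)[None, :]
    return d


def _ray_extents(
    centers: np.ndarray, directions: np.ndarray, atom_xyz: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Farthest ray/vdW-sphere intersection parameter per (center, ray).

    centers (..., 3) broadcast against directions (..., 3); returns t >= 0
    (0 where no sphere is hit).  Solves |c + t d - R_a|^2 = r_a^2 for every
    atom a and keeps the largest non-negative root.
    """
    u = atom_xyz[None, :, :] - centers[..., None, :]  # (M, n_atoms, 3)
    b = np.einsum("...d,...ad->...a", directions, u)
    q = np.einsum("...ad,...ad->...a", u, u) - radii[None, :] ** 2
    disc = b * b - q
    hit = disc >= 0.0
    root = np.where(hit, b + np.sqrt(np.where(hit, disc, 0.0)), -np.inf)
    extent = np.max(np.where(root >= 0.0, root, -np.inf), axis=-1)
    return np.where(np.isfinite(extent), extent, 0.0)


def ray_vdw_extent(
    mol: Molecule3D,
    center: np.ndarray,
    direction: np.ndarray,
    radii_table: dict[str, float] | None = None,
) -> float:
    """Distance from ``center`` to the outermost vdW-surface point along a ray."""
    cfg_table = radii_table or BONDI_VDW_RADII
    radii = np.array([cfg_table[s] for s in mol.symbols])
    c = np.asarray(center, dtype=float).reshape(1, 3)
    d = np.asarray(direction, dtype=float).reshape(1, 3)
    d = d / np.linalg.norm(d)
    return float(_ray_extents(c, d, mol.coords, radii)[0])


def spms_matrix(
    mol: Molecule3D, center_atom: int, cfg: StericConfig | None = None
) -> StericMatrix:
    """Equirectangular steric map centered on one atom.

    Entry (i, j) = radius - extent along the bin-center direction
    (theta_i, phi_j).  Entries are clamped to [0, radius]; an extent beyond
    the sphere radius is clamped to 0 with a warning (the molecule pokes
    out of the reference sphere).
    """
    cfg = cfg or StericConfig()
    if not (0 <= center_atom < mol.n_atoms):
        raise ValidationError(f"center_atom {center_atom} out of range")
    radii = np.array([cfg.vdw_radius(s) for s in mol.symbols])
    dirs = grid_directions(cfg.n_polar).reshape(-1, 3)
    center = np.broadcast_to(mol.coords[center_atom], dirs.shape)
    extents = _ray_extents(center, dirs, mol.coords, radii)
    if extents.max() > cfg.radius:
        logger.warning(
            "molecule extends beyond the %.1f A sphere (max extent %.2f A); clamping",
            cfg.radius,
            extents.max(),
        )
    values = np.clip(cfg.radius - extents, 0.0, cfg.radius)
    return StericMatrix(values.reshape(cfg.n_polar, 2 * cfg.n_polar), center_atom)


def steric_stack(
    mol: Molecule3D, cfg: StericConfig | None = None
) -> list[StericMatrix]:
    """One steric map per atom, in atom order."""
    if mol.n_atoms == 0:
        raise ValidationError("cannot compute steric maps of an empty molecule")
    cfg = cfg or StericConfig()
    return [spms_matrix(mol, i, cfg) for i in range(mol.n_atoms)]
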