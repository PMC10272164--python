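"""Per-atom electron-density grids.

Each atom is assigned a cube whose side equals the atom's van der Waals
diameter, partitioned into 7 x 7 x 7 cells; the electron density evaluated
at the cell centers forms the atom's electronic tensor (e/Bohr^3).

The default density backend is a promolecule model: the molecular density
is approximated as a sum of spherical atomic densities
rho_a(r) = c_a exp(-r/lambda_a), with lambda_a from Slater-rule valence
exponents and c_a normalised so each atom integrates to its electron
count.  This keeps the encoding's information content — element identity
plus the local molecular environment — while remaining instantaneous to
evaluate.  A quantum-chemistry backend can be plugged in through
:func:`external_qm_density`; the two are unit-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Molecule3D
from .constants import (
    ANGSTROM_TO_BOHR,
    BONDI_VDW_RADII,
    PROMOLECULE_LAMBDA_BOHR,
    promolecule_coefficient,
)
from .errors import ConfigurationError, ValidationError

GRID_PER_AXIS = 7


@dataclass
class ElectronicConfig:
    """Grid resolution and density backend selection.

    ``grid_per_axis`` is fixed at 7 by the encoding definition; the cube
    side is always the vdW diameter of the center atom.  Backends:
    ``promolecule`` (default), ``external_qm`` (opt-in contract), ``zero``.
    """

    grid_per_axis: int = GRID_PER_AXIS
    backend: str = "promolecule"
    radii_table: dict | None = None

    def __post_init__(self) -> None:
        if self.grid_per_axis < 1:
            raise ConfigurationError("grid_per_axis must be positive")
        if self.backend not in ("promolecule", "external_qm", "zero"):
            raise ConfigurationError(f"unknown density backend {self.backend!r}")

    def vdw_radius(self, symbol: str) -> float:
        table = self.radii_table or BONDI_VDW_RADII
        try:
            return table[symbol]
        except KeyError as exc:
            raise ConfigurationError(
                f"no van der Waals radius for element {symbol!r}"
            ) from exc


@dataclass
class ElectronicTensor:
    """7 x 7 x 7 non-negative densities (e/Bohr^3) around one atom."""

    values: np.ndarray
    center_atom: int


def cube_points(center: np.ndarray, side: float, n: int = GRID_PER_AXIS) -> np.ndarray:
    """Ordered cell centers of an n^3 uniform cube partition, shape (n^3, 3).

    Per-axis offsets are ((k + 1/2)/n - 1/2) * side for k = 0..n-1.  The
    flat ordering is x-fastest, then y, then z: point p = iz*n^2 + iy*n + ix.
    """
    if side <= 0:
        raise ValidationError("cube side must be positive")
    center = np.asarray(center, dtype=float)
    offs = ((np.arange(n) + 0.5) / n - 0.5) * side
    zz, yy, xx = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    return pts + center[None, :]


def promolecule_density(mol: Molecule3D, points: np.ndarray) -> np.ndarray:
    """Promolecule electron density (e/Bohr^3) at Cartesian points (A)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    out = np.zeros(len(points))
    for sym, num, xyz in zip(mol.symbols, mol.atomic_numbers, mol.coords):
        if sym not in PROMOLECULE_LAMBDA_BOHR:
            raise ConfigurationError(
                f"element {sym!r} missing from the promolecule parameter table"
            )
        lam = PROMOLECULE_LAMBDA_BOHR[sym]
        c = promolecule_coefficient(sym, int(num))
        r_bohr = np.linalg.norm(points - xyz[None, :], axis=1) * ANGSTROM_TO_BOHR
        out += c * np.exp(-r_bohr / lam)
    return out


def external_qm_density(
    mol: Molecule3D, points: np.ndarray, level: str = "B3LYP/def2-SVP"
) -> np.ndarray:
    """Ab initio density at the given points (contract; requires PySCF).

    When a quantum-chemistry backend is importable this runs a single-point
    calculation at ``level`` and evaluates the converged density on the
    grid.  Without one it raises :class:`ConfigurationError` advising the
    promolecule backend; the rest of the package never requires it.
    """
    try:
        import pyscf  # noqa: F401
        from pyscf import dft, gto
    except ImportError as exc:
        raise ConfigurationError(
            "no quantum-chemistry backend importable (pyscf); "
            "use the promolecule density backend instead"
        ) from exc
    functional, basis = level.split("/")
    mole = gto.M(
        atom=[(s, tuple(c)) for s, c in zip(mol.symbols, mol.coords)],
        basis=basis,
        unit="Angstrom",
        verbose=0,
    )
    mf = dft.RKS(mole, xc=functional)
    mf.kernel()
    dm = mf.make_rdm1()
    pts_bohr = np.asarray(points, float).reshape(-1, 3) * ANGSTROM_TO_BOHR
    ao = mole.eval_gto("GTOval", pts_bohr)
    return np.einsum("pi,ij,pj->p", ao, dm, ao)


def electronic_tensor(
    mol: Molecule3D, atom_index: int, cfg: ElectronicConfig | None = None
) -> ElectronicTensor:
    """Density tensor on the vdW-diameter cube of one atom.

    ``values[ix, iy, iz]`` is the backend density at the cell center with
    x-offset index ix etc.; the box side is twice the center element's vdW
    radius.
    """
    cfg = cfg or ElectronicConfig()
    if not (0 <= atom_index < mol.n_atoms):
        raise ValidationError(f"atom_index {atom_index} out of range")
    n = cfg.grid_per_axis
    side = 2.0 * cfg.vdw_radius(mol.symbols[atom_index])
    pts = cube_points(mol.coords[atom_index], side, n)
    if cfg.backend == "zero":
        dens = np.zeros(len(pts))
    elif cfg.backend == "promolecule":
        dens = promolecule_density(mol, pts)
    else:
        dens = external_qm_density(mol, pts)
    if not np.all(np.isfinite(dens)):
        raise ConfigurationError(
            f"density backend {cfg.backend!r} returned non-finite values "
            f"for atom {atom_index}"
        )
    # flat order is x-fastest -> reshape to (z, y, x) then transpose
    values = dens.reshape(n, n, n).transpose(2, 1, 0)
    return ElectronicTensor(values, atom_index)


def electronic_stack(
    mol: Molecule3D, cfg: ElectronicConfig | None = None
) -> list[ElectronicTensor]:
    """One density tensor per atom, in atom order."""
    if mol.n_atoms == 0:
        raise ValidationError("cannot compute density tensors of an empty molecule")
    cfg = cfg or ElectronicConfig()
    return [electronic_tensor(mol, i, cfg) for i in range(mol.n_atoms)]
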