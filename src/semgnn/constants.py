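"""Physical constants and per-element parameter tables.

All geometric quantities in the package are in Angstrom; electron densities
are in e/Bohr^3, matching the quantum-chemistry convention so that a future
ab initio density backend is drop-in interchangeable with the built-in
promolecule model.
"""

from __future__ import annotations

import math

ANGSTROM_TO_BOHR = 1.8897259886

# Bondi van der Waals radii (Angstrom).  This table is the single source of
# truth for both the steric sphere projection and the electronic cube side
# (vdW diameter).  Values: Bondi, J. Phys. Chem. 68 (1964) 441, plus the
# common extensions for heavier main-group elements.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "Li": 1.81,
    "Be": 1.53,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Al": 1.84,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Zn": 1.39,
    "Ga": 1.87,
    "Ge": 2.11,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "I": 1.98,
    "Xe": 2.16,
}

# Valence decay lengths lambda_a (Bohr) for the promolecule density model
# rho_a(r) = c_a * exp(-r / lambda_a).  Derived from Slater's rules for the
# outermost shell, lambda = n*/(2 zeta); c_a is fixed by normalising the
# spherical integral 8 pi lambda^3 c_a to the element's electron count.
PROMOLECULE_LAMBDA_BOHR: dict[str, float] = {
    "H": 0.500,
    "B": 0.769,
    "C": 0.615,
    "N": 0.513,
    "O": 0.440,
    "F": 0.385,
    "Na": 1.100,
    "Mg": 0.900,
    "Si": 0.917,
    "P": 0.797,
    "S": 0.707,
    "Cl": 0.637,
    "Br": 0.718,
    "I": 0.775,
}


def promolecule_coefficient(symbol: str, n_electrons: int) -> float:
    """Prefactor c_a (e/Bohr^3) normalising rho_a to ``n_electrons``."""
    lam = PROMOLECULE_LAMBDA_BOHR[symbol]
    return n_electrons / (8.0 * math.pi * lam**3)
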