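"""Molecular structure and reaction-table I/O.

Molecules are held as :class:`Molecule3D` — one conformer with explicit
hydrogens, 0-based atom indexing and a component-role tag.  Conformers are
generated with RDKit's ETKDG method and optionally relaxed with an
in-process force field or an external tight-binding optimizer.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import (
    ConfigurationError,
    EmbedError,
    ParseError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("semgnn.chemio")

_PT = Chem.GetPeriodicTable()


@dataclass
class Molecule3D:
    """A single 3-D conformer with explicit hydrogens.

    Attributes
    ----------
    symbols : list of element symbols, one per atom.
    coords : (n_atoms, 3) Cartesian coordinates in Angstrom.
    bonds : list of (i, j, order) with 0-based indices; order is the
        conventional bond order (1.5 for aromatic).
    role : component-role label within a reaction (free string).
    provenance : source note (SMILES or file path).
    reactive_atom : optional 0-based index of the annotated reactive site,
        used by the synthetic-data generator.
    """

    symbols: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    role: str = ""
    provenance: str = ""
    reactive_atom: int | None = None
    formal_charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.formal_charges is not None:
            self.formal_charges = np.asarray(self.formal_charges, dtype=int)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.coords) != len(self.symbols):
            raise ValidationError(
                f"coordinate count {len(self.coords)} != atom count {len(self.symbols)}"
            )
        n = len(self.symbols)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) out of range for {n} atoms")
        if n > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-6:
                raise ValidationError("two atoms share identical coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([_PT.GetAtomicNumber(s) for s in self.symbols], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_PT.GetAtomicWeight(s) for s in self.symbols])

    def with_coords(self, coords: np.ndarray) -> "Molecule3D":
        return replace(self, coords=np.asarray(coords, dtype=np.float64).copy())

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild an RDKit molecule (with conformer) from this record."""
        em = Chem.RWMol()
        for i, s in enumerate(self.symbols):
            atom = Chem.Atom(s)
            if self.formal_charges is not None:
                atom.SetFormalCharge(int(self.formal_charges[i]))
            em.AddAtom(atom)
        for i, j, order in self.bonds:
            bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                  3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}[float(order)]
            em.AddBond(int(i), int(j), bt)
        mol = em.GetMol()
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - charged/exotic species
            Chem.SanitizeMol(
                mol, sanitizeOps=Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            )
        return mol

    @classmethod
    def from_rdkit(
        cls,
        mol: Chem.Mol,
        role: str = "",
        provenance: str = "",
        reactive_atom: int | None = None,
    ) -> "Molecule3D":
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        bonds = []
        for b in mol.GetBonds():
            order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], dtype=int)
        return cls(symbols, coords, bonds, role, provenance, reactive_atom, charges)


@dataclass
class ReactionRecord:
    """One reaction: ordered role -> molecule mapping plus its outcome.

    ``target_kind`` is ``"yield"`` (percent, in [0, 100]) or ``"ddg"``
    (differential activation free energy, kcal/mol).  Role order is fixed by
    the dataset schema and is significant downstream: the model concatenates
    component representations in this order.
    """

    components: dict[str, Molecule3D]
    target: float
    target_kind: str = "yield"

    def __post_init__(self) -> None:
        if self.target_kind not in ("yield", "ddg"):
            raise ValidationError(f"unknown target_kind {self.target_kind!r}")
        if not np.isfinite(self.target):
            raise ValidationError("target must be finite")
        if self.target_kind == "yield" and not (0.0 <= self.target <= 100.0):
            raise ValidationError(f"yield {self.target} outside [0, 100]")

    @property
    def roles(self) -> list[str]:
        return list(self.components)

    @property
    def molecules(self) -> list[Molecule3D]:
        return list(self.components.values())


# ---------------------------------------------------------------------------
# Conformer generation and geometry optimization
# ---------------------------------------------------------------------------

def embed_3d(smiles: str, seed: int = 0, role: str = "") -> Molecule3D:
    """Generate one seeded ETKDG conformer with explicit hydrogens.

    Deterministic for a fixed (smiles, seed).  Raises :class:`ParseError`
    for unparseable SMILES and :class:`EmbedError` if embedding fails even
    after a random-coordinate retry.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EmbedError(f"3-D embedding failed for {smiles!r}")
    return Molecule3D.from_rdkit(mol, role=role, provenance=smiles)


def optimize_geometry(mol: Molecule3D, backend: str = "forcefield") -> Molecule3D:
    """Relax a geometry with the selected backend; atom order is preserved.

    Backends: ``none`` returns the input unchanged; ``forcefield`` runs the
    MMFF94 minimizer in-process (UFF if MMFF parameters are missing);
    ``external_xtb`` shells out to an installed ``xtb`` binary through an
    XYZ round-trip and raises :class:`ConfigurationError` when the binary is
    not on PATH.
    """
    if backend == "none":
        return mol.with_coords(mol.coords)
    if backend == "forcefield":
        rd = mol.to_rdkit()
        if AllChem.MMFFHasAllMoleculeParams(rd):
            converged = AllChem.MMFFOptimizeMolecule(rd, maxIters=2000)
        else:
            converged = AllChem.UFFOptimizeMolecule(rd, maxIters=2000)
        if converged != 0:
            logger.warning("force-field optimization did not fully converge")
        conf = rd.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(rd.GetNumAtoms())])
        return mol.with_coords(coords)
    if backend == "external_xtb":
        exe = shutil.which("xtb")
        if exe is None:
            raise ConfigurationError(
                "xtb binary not found on PATH; install xtb or use backend='forcefield'"
            )
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.xyz"
            write_xyz(mol, inp)
            subprocess.run(
                [exe, str(inp), "--opt"], cwd=tmp, check=True,
                capture_output=True, text=True,
            )
            out = Path(tmp) / "xtbopt.xyz"
            opt = read_xyz(out)
        return mol.with_coords(opt.coords)
    raise ConfigurationError(f"unknown geometry backend {backend!r}")


# ---------------------------------------------------------------------------
# SDF / XYZ
# ---------------------------------------------------------------------------

def write_sdf(mol: Molecule3D, path: str | Path) -> None:
    """Write a single-molecule V2000 SDF (1-based indices on disk)."""
    rd = mol.to_rdkit()
    with Chem.SDWriter(str(path)) as w:
        w.write(rd)


def read_sdf(path: str | Path, role: str = "") -> Molecule3D:
    """Read the first molecule of a V2000 SDF, hydrogens kept as written."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mol = next(iter(supplier), None)
    if mol is None:
        raise ParseError(f"malformed SDF block starting at line 1 of {path}")
    return Molecule3D.from_rdkit(mol, role=role, provenance=str(path))


def write_xyz(mol: Molecule3D, path: str | Path) -> None:
    lines = [str(mol.n_atoms), mol.provenance or "semgnn"]
    for s, (x, y, z) in zip(mol.symbols, mol.coords):
        lines.append(f"{s} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, role: str = "") -> Molecule3D:
    """Read a plain XYZ file (no bonds)."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ParseError(f"{path}: empty XYZ file (line 1)")
    try:
        n = int(raw[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: bad atom-count line (line 1)") from exc
    body = [ln for ln in raw[2:] if ln.strip()]
    if len(body) != n:
        raise ParseError(
            f"{path}: count line says {n} atoms but {len(body)} coordinate "
            f"rows found (line {2 + len(body) + 1})"
        )
    symbols, coords = [], []
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed coordinate row (line {k + 3})")
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return Molecule3D(symbols, np.array(coords), role=role, provenance=str(path))


# ---------------------------------------------------------------------------
# Reaction tables
# ---------------------------------------------------------------------------

def load_schema(schema: str | Path | Mapping) -> dict:
    """Load a role-column schema mapping from a dict or JSON/YAML file.

    Expected keys: ``roles`` (ordered mapping role -> SMILES column),
    ``target`` (target column), ``target_kind`` ("yield" or "ddg") and an
    optional ``embed_seed`` for conformer generation.
    """
    if isinstance(schema, Mapping):
        sd = dict(schema)
    else:
        text = Path(schema).read_text()
        if str(schema).endswith((".yaml", ".yml")):
            import yaml

            sd = yaml.safe_load(text)
        else:
            sd = json.loads(text)
    for key in ("roles", "target"):
        if key not in sd:
            raise SchemaError(f"schema missing required key {key!r}")
    sd.setdefault("target_kind", "yield")
    sd.setdefault("embed_seed", 0)
    return sd


def read_reaction_table(
    path: str | Path,
    schema: str | Path | Mapping,
    optimize: str = "none",
    _molecule_cache: dict | None = None,
) -> list[ReactionRecord]:
    """Read a delimited reaction table into :class:`ReactionRecord` objects.

    One record per row.  Rows with a missing SMILES or a non-numeric target
    are skipped with a logged warning carrying the row index; a numeric
    yield outside [0, 100] raises :class:`ValidationError`.  Identical
    SMILES share one embedded conformer via an internal cache, so component
    molecules are consistent across reactions.
    """
    sd = load_schema(schema)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for role, col in sd["roles"].items():
        if col not in df.columns:
            raise SchemaError(f"schema column {col!r} (role {role!r}) not in table")
    if sd["target"] not in df.columns:
        raise SchemaError(f"target column {sd['target']!r} not in table")

    cache = _molecule_cache if _molecule_cache is not None else {}
    seed = int(sd["embed_seed"])
    records: list[ReactionRecord] = []
    for idx, row in df.iterrows():
        target = pd.to_numeric(row[sd["target"]], errors="coerce")
        if pd.isna(target):
            logger.warning("row %d skipped: non-numeric target %r", idx, row[sd["target"]])
            continue
        smiles = {role: row[col] for role, col in sd["roles"].items()}
        if any(pd.isna(s) or not str(s).strip() for s in smiles.values()):
            logger.warning("row %d skipped: missing SMILES", idx)
            continue
        components = {}
        for role, smi in smiles.items():
            key = (str(smi), seed, optimize)
            if key not in cache:
                m = embed_3d(str(smi), seed=seed, role=role)
                if optimize != "none":
                    m = optimize_geometry(m, backend=optimize)
                cache[key] = m
            components[role] = replace(cache[key], role=role)
        records.append(
            ReactionRecord(components, float(target), target_kind=sd["target_kind"])
        )
    return records


def write_reaction_table(
    records: Sequence[ReactionRecord], path: str | Path, schema: Mapping
) -> None:
    """Serialize records back to a delimited table matching ``schema``."""
    sd = load_schema(schema)
    rows = []
    for rec in records:
        row = {col: rec.components[role].provenance for role, col in sd["roles"].items()}
        row[sd["target"]] = rec.target
        rows.append(row)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
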