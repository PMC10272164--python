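"""Assembly of steric/electronics-embedded molecular graphs (SEMG).

A SEMG is an ordinary molecular graph (atoms as nodes, bonds as edges, no
edge attributes) whose every node carries two dense encodings of its local
environment: a 10 x 20 steric distance map and a 7 x 7 x 7 electron-density
tensor.  A classic hand-featured graph (``BaselineGraph``) is kept as the
ablation control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Molecule3D
from .electronic import ElectronicConfig, ElectronicTensor, electronic_stack
from .errors import AssemblyError, SizeError, ValidationError
from .orientation import standardize_orientation
from .steric import StericConfig, StericMatrix, steric_stack

ELEMENT_VOCAB = ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
# one-hot element (+other) | atomic number | degree | formal charge |
# aromatic | H-bond donor | H-bond acceptor
BASELINE_FEATURE_LENGTH = len(ELEMENT_VOCAB) + 1 + 6


@dataclass
class SEMGGraph:
    """Molecular graph with per-node steric and electronic encodings."""

    n_atoms: int
    edges: list[tuple[int, int]]
    node_steric: np.ndarray  # (n_atoms, N, 2N)
    node_electronic: np.ndarray  # (n_atoms, 7, 7, 7)
    role: str = ""

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass
class BaselineGraph:
    """Classic molecular graph with fixed-length topological node features."""

    n_atoms: int
    edges: list[tuple[int, int]]
    node_features: np.ndarray  # (n_atoms, BASELINE_FEATURE_LENGTH)
    role: str = ""

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


def _edges(mol: Molecule3D) -> list[tuple[int, int]]:
    seen = set()
    edges = []
    for i, j, _ in mol.bonds:
        key = (min(i, j), max(i, j))
        if key not in seen and i != j:
            seen.add(key)
            edges.append(key)
    return edges


def build_semg(
    mol: Molecule3D,
    steric: list[StericMatrix],
    electronic: list[ElectronicTensor],
) -> SEMGGraph:
    """Attach precomputed per-atom encodings to the molecular graph.

    The stacks must have been computed on the standardized geometry and
    have exactly one entry per atom, in atom order.
    """
    if len(steric) != mol.n_atoms or len(electronic) != mol.n_atoms:
        raise AssemblyError(
            f"stack lengths ({len(steric)}, {len(electronic)}) != "
            f"atom count {mol.n_atoms}"
        )
    return SEMGGraph(
        n_atoms=mol.n_atoms,
        edges=_edges(mol),
        node_steric=np.stack([m.values for m in steric]),
        node_electronic=np.stack([t.values for t in electronic]),
        role=mol.role,
    )


def encode_molecule(
    mol: Molecule3D,
    steric_cfg: StericConfig | None = None,
    electronic_cfg: ElectronicConfig | None = None,
    standardize: bool = True,
) -> SEMGGraph:
    """Full encoding pipeline: standardize pose, then embed both channels."""
    posed = standardize_orientation(mol)[0] if standardize else mol
    return build_semg(
        posed,
        steric_stack(posed, steric_cfg),
        electronic_stack(posed, electronic_cfg),
    )


def build_baseline(mol: Molecule3D) -> BaselineGraph:
    """Classic-feature graph: topology-only node descriptors.

    Features per atom: one-hot element over a pinned vocabulary (unknown
    elements map to an ``other`` slot), atomic number, degree, formal
    charge, aromatic flag, and rule-based H-bond donor/acceptor flags
    (donor: N/O bearing >= 1 H; acceptor: neutral N/O).
    """
    n = mol.n_atoms
    if n == 0:
        raise ValidationError("cannot featurize an empty molecule")
    feats = np.zeros((n, BASELINE_FEATURE_LENGTH))
    degree = np.zeros(n, dtype=int)
    h_neighbors = np.zeros(n, dtype=int)
    aromatic = np.zeros(n, dtype=bool)
    for i, j, order in mol.bonds:
        degree[i] += 1
        degree[j] += 1
        if mol.symbols[j] == "H":
            h_neighbors[i] += 1
        if mol.symbols[i] == "H":
            h_neighbors[j] += 1
        if float(order) == 1.5:
            aromatic[i] = aromatic[j] = True
    charges = (
        mol.formal_charges if mol.formal_charges is not None else np.zeros(n, int)
    )
    nums = mol.atomic_numbers
    base = len(ELEMENT_VOCAB) + 1
    for a, sym in enumerate(mol.symbols):
        slot = ELEMENT_VOCAB.index(sym) if sym in ELEMENT_VOCAB else len(ELEMENT_VOCAB)
        feats[a, slot] = 1.0
        feats[a, base + 0] = float(nums[a])
        feats[a, base + 1] = float(degree[a])
        feats[a, base + 2] = float(charges[a])
        feats[a, base + 3] = float(aromatic[a])
        is_no = sym in ("N", "O")
        feats[a, base + 4] = float(is_no and h_neighbors[a] >= 1)
        feats[a, base + 5] = float(is_no and charges[a] <= 0)
    return BaselineGraph(n, _edges(mol), feats, role=mol.role)


def pad_batch(graphs: list, max_atoms: int) -> dict[str, np.ndarray]:
    """Zero-pad per-node arrays to a common atom count, with validity mask.

    Works for both graph flavours.  Returns ``mask`` (B, max_atoms) plus,
    per flavour, ``steric``/``electronic`` or ``features``, and the padded
    ``adjacency``.  A graph larger than ``max_atoms`` raises
    :class:`SizeError` — never silent truncation.
    """
    b = len(graphs)
    for g in graphs:
        if g.n_atoms > max_atoms:
            raise SizeError(f"graph with {g.n_atoms} atoms exceeds max_atoms={max_atoms}")
    mask = np.zeros((b, max_atoms), dtype=bool)
    adj = np.zeros((b, max_atoms, max_atoms))
    for k, g in enumerate(graphs):
        mask[k, : g.n_atoms] = True
        adj[k, : g.n_atoms, : g.n_atoms] = g.adjacency()
    out: dict[str, np.ndarray] = {"mask": mask, "adjacency": adj}
    if isinstance(graphs[0], SEMGGraph):
        ns, ne = graphs[0].node_steric.shape[1:], graphs[0].node_electronic.shape[1:]
        steric = np.zeros((b, max_atoms, *ns))
        electronic = np.zeros((b, max_atoms, *ne))
        for k, g in enumerate(graphs):
            steric[k, : g.n_atoms] = g.node_steric
            electronic[k, : g.n_atoms] = g.node_electronic
        out["steric"] = steric
        out["electronic"] = electronic
    else:
        d = graphs[0].node_features.shape[1]
        feats = np.zeros((b, max_atoms, d))
        for k, g in enumerate(graphs):
            feats[k, : g.n_atoms] = g.node_features
        out["features"] = feats
    return out
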