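"""HDF5 container for per-molecule encodings.

Layout: ``/<dataset_id>/<molecule_id>/steric`` (n_atoms, N, 2N) and
``.../electronic`` (n_atoms, 7, 7, 7), with the SMILES provenance and role
stored as attributes.  One file can hold many datasets.
"""

from __future__ import annotations

import h5py
import numpy as np

from .semg import SEMGGraph


class EncodingStore:
    """Read/write access to an encodings HDF5 file."""

    def __init__(self, path: str, mode: str = "a"):
        self.path = str(path)
        self.mode = mode

    def save(self, dataset_id: str, molecule_id: str, graph: SEMGGraph,
             provenance: str = "") -> None:
        with h5py.File(self.path, self.mode) as f:
            grp = f.require_group(dataset_id).require_group(molecule_id)
            for name in ("steric", "electronic"):
                if name in grp:
                    del grp[name]
            grp.create_dataset("steric", data=graph.node_steric)
            grp.create_dataset("electronic", data=graph.node_electronic)
            grp.attrs["role"] = graph.role
            grp.attrs["provenance"] = provenance
            grp.attrs["n_atoms"] = graph.n_atoms
            grp.attrs["edges"] = np.array(graph.edges, dtype=np.int64).reshape(-1, 2)

    def load(self, dataset_id: str, molecule_id: str) -> SEMGGraph:
        with h5py.File(self.path, "r") as f:
            grp = f[dataset_id][molecule_id]
            edges = [tuple(e) for e in grp.attrs["edges"].tolist()]
            return SEMGGraph(
                n_atoms=int(grp.attrs["n_atoms"]),
                edges=edges,
                node_steric=grp["steric"][()],
                node_electronic=grp["electronic"][()],
                role=str(grp.attrs["role"]),
            )

    def molecule_ids(self, dataset_id: str) -> list[str]:
        with h5py.File(self.path, "r") as f:
            return sorted(f[dataset_id].keys())
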