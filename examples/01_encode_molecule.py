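"""Encode one molecule: conformer, canonical pose, steric map, density grid.

The steric map entry is the gap (in Angstrom) between a 10 A reference
sphere and the molecular vdW surface along each direction — small values
mean bulk on that side.  The electronic tensor holds promolecule electron
densities (e/Bohr^3) on a 7x7x7 grid spanning the atom's vdW cube.
"""

import numpy as np

from semgnn import embed_3d, encode_molecule, optimize_geometry, standardize_orientation

mol = embed_3d("Clc1ccc(C(F)(F)F)cc1", seed=0)   # 1-chloro-4-(trifluoromethyl)benzene
mol = optimize_geometry(mol, backend="forcefield")
posed, frame = standardize_orientation(mol)
print(f"{mol.n_atoms} atoms; key atoms: {frame.atom1_index} -> +z, "
      f"{frame.atom2_index} -> yz plane")

graph = encode_molecule(mol)
cl = mol.symbols.index("Cl")
steric = graph.node_steric[cl]
density = graph.node_electronic[cl]
print(f"steric map of Cl: shape {steric.shape}, "
      f"min {steric.min():.2f} A (most crowded direction), "
      f"max {steric.max():.2f} A (most open)")
print(f"density tensor of Cl: shape {density.shape}, "
      f"central cell {density[3, 3, 3]:.3f} e/Bohr^3, "
      f"corner cell {density[0, 0, 0]:.5f} e/Bohr^3")
print("ring side of the map is more crowded than the open side:",
      steric.mean(axis=1).round(2))
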