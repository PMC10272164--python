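import numpy as np
import pytest

from semgnn.chemio import (
    Molecule3D,
    embed_3d,
    load_schema,
    optimize_geometry,
    read_reaction_table,
    read_sdf,
    read_xyz,
    write_reaction_table,
    write_sdf,
    write_xyz,
)
from semgnn.errors import (
    ConfigurationError,
    ParseError,
    SchemaError,
    ValidationError,
)


class TestEmbed3D:
    def test_h2_bond_length_in_covalent_window(self):
        mol = embed_3d("[H][H]", seed=0)
        assert mol.n_atoms == 2
        d = np.linalg.norm(mol.coords[0] - mol.coords[1])
        # H-H covalent distance is 0.74 A; a raw distance-geometry
        # conformer lands near it
        assert 0.6 < d < 0.9

    def test_methane_has_explicit_hydrogens(self, methane):
        assert methane.n_atoms == 5
        assert sorted(methane.symbols) == ["C", "H", "H", "H", "H"]

    def test_deterministic_for_fixed_seed(self):
        a = embed_3d("CCO", seed=3)
        b = embed_3d("CCO", seed=3)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self):
        a = embed_3d("CCO", seed=0)
        b = embed_3d("CCO", seed=42)
        assert not np.allclose(a.coords, b.coords)

    def test_unparseable_smiles(self):
        with pytest.raises(ParseError):
            embed_3d("not-a-smiles", seed=0)


class TestOptimizeGeometry:
    def test_none_backend_is_identity(self, methane):
        out = optimize_geometry(methane, backend="none")
        assert np.array_equal(out.coords, methane.coords)

    def test_forcefield_symmetrizes_methane(self, methane):
        distorted = methane.with_coords(
            methane.coords + np.random.default_rng(0).normal(0, 0.15, (5, 3))
        )
        relaxed = optimize_geometry(distorted, backend="forcefield")
        c = relaxed.symbols.index("C")
        lengths = [
            np.linalg.norm(relaxed.coords[i] - relaxed.coords[c])
            for i in range(5)
            if i != c
        ]
        assert max(lengths) - min(lengths) < 0.02

    def test_missing_xtb_binary_raises_configuration_error(self, methane):
        with pytest.raises(ConfigurationError, match="xtb"):
            optimize_geometry(methane, backend="external_xtb")

    def test_atom_order_preserved(self, water):
        out = optimize_geometry(water, backend="forcefield")
        assert out.symbols == water.symbols


class TestStructureFiles:
    def test_sdf_round_trip(self, tmp_path, water):
        path = tmp_path / "water.sdf"
        write_sdf(water, path)
        back = read_sdf(path)
        assert back.symbols == water.symbols
        assert len(back.bonds) == len(water.bonds)
        assert np.allclose(back.coords, water.coords, atol=1e-4)

    def test_sdf_bond_indices_are_zero_based(self, tmp_path, water):
        write_sdf(water, tmp_path / "w.sdf")
        back = read_sdf(tmp_path / "w.sdf")
        idx = [i for b in back.bonds for i in b[:2]]
        assert min(idx) == 0 and max(idx) < back.n_atoms

    def test_xyz_round_trip(self, tmp_path, methane):
        path = tmp_path / "methane.xyz"
        write_xyz(methane, path)
        back = read_xyz(path)
        assert back.symbols == methane.symbols
        assert np.allclose(back.coords, methane.coords, atol=1e-4)

    def test_xyz_count_mismatch(self, tmp_path):
        (tmp_path / "bad.xyz").write_text("3\ncomment\nH 0 0 0\nH 0 0 1\n")
        with pytest.raises(ParseError, match="count"):
            read_xyz(tmp_path / "bad.xyz")


SCHEMA = {
    "roles": {"aryl_halide": "halide", "amine": "amine"},
    "target": "yield",
    "target_kind": "yield",
    "embed_seed": 0,
}


def _write_table(path, rows):
    lines = ["halide,amine,yield"] + rows
    path.write_text("\n".join(lines) + "\n")


class TestReactionTable:
    def test_row_and_component_counts(self, tmp_path):
        table = tmp_path / "t.csv"
        _write_table(table, [
            "Clc1ccccc1,Nc1ccccc1,55.0",
            "Clc1ccccc1,CN,21.5",
            "Brc1ccccc1,Nc1ccccc1,90.0",
        ])
        records = read_reaction_table(table, SCHEMA)
        assert len(records) == 3
        assert all(len(r.components) == 2 for r in records)
        assert records[0].roles == ["aryl_halide", "amine"]

    def test_non_numeric_target_skipped(self, tmp_path):
        table = tmp_path / "t.csv"
        _write_table(table, ["Clc1ccccc1,CN,n/a", "Clc1ccccc1,CN,50"])
        records = read_reaction_table(table, SCHEMA)
        assert len(records) == 1

    def test_missing_smiles_skipped(self, tmp_path):
        table = tmp_path / "t.csv"
        _write_table(table, ["Clc1ccccc1,,50", "Clc1ccccc1,CN,50"])
        assert len(read_reaction_table(table, SCHEMA)) == 1

    def test_out_of_range_yield_rejected(self, tmp_path):
        table = tmp_path / "t.csv"
        _write_table(table, ["Clc1ccccc1,CN,103.0"])
        with pytest.raises(ValidationError, match="103"):
            read_reaction_table(table, SCHEMA)

    def test_missing_schema_column(self, tmp_path):
        table = tmp_path / "t.csv"
        table.write_text("only_one_column\nx\n")
        with pytest.raises(SchemaError):
            read_reaction_table(table, SCHEMA)

    def test_serialization_round_trip(self, tmp_path):
        table = tmp_path / "t.csv"
        _write_table(table, ["Clc1ccccc1,CN,55.0", "Brc1ccccc1,CN,12.5"])
        records = read_reaction_table(table, SCHEMA)
        out = tmp_path / "o.csv"
        write_reaction_table(records, out, SCHEMA)
        again = read_reaction_table(out, SCHEMA)
        assert [r.target for r in again] == [r.target for r in records]
        assert [
            m.provenance for r in again for m in r.molecules
        ] == [m.provenance for r in records for m in r.molecules]

    def test_schema_requires_roles_key(self, tmp_path):
        with pytest.raises(SchemaError):
            load_schema({"target": "yield"})


class TestMolecule3DInvariants:
    def test_coordinate_atom_count_mismatch(self):
        with pytest.raises(ValidationError):
            Molecule3D(["H", "H"], np.zeros((3, 3)))

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            Molecule3D(["H", "H"], np.zeros((2, 3)))

    def test_bond_index_out_of_range(self):
        with pytest.raises(ValidationError):
            Molecule3D(["H", "H"], [[0, 0, 0], [0, 0, 1]], bonds=[(0, 5, 1.0)])
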