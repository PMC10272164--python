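import numpy as np
import pytest

from semgnn import nn
from semgnn.errors import CapabilityError
from semgnn.mignn import (
    GCN,
    MIGNN,
    ModelConfig,
    _InteractionModule,
    featurize_records,
    slice_features,
)
from semgnn.orientation import standardize_orientation


@pytest.fixture(scope="module")
def small_batch(tiny_dataset):
    records, _ = tiny_dataset
    return featurize_records(records[:4])


@pytest.fixture(scope="module")
def model(small_batch):
    cfg = ModelConfig(seed=0)
    return MIGNN(m=2, max_atoms=small_batch["max_atoms"], cfg=cfg)


class TestForwardContracts:
    def test_prediction_shape_and_finiteness(self, model, small_batch):
        out = model.predict(small_batch)
        assert out.shape == (4,)
        assert np.all(np.isfinite(out))

    def test_deterministic_under_fixed_seed(self, small_batch):
        cfg = ModelConfig(seed=1)
        a = MIGNN(2, small_batch["max_atoms"], cfg).predict(small_batch)
        b = MIGNN(2, small_batch["max_atoms"], cfg).predict(small_batch)
        assert np.array_equal(a, b)

    def test_zero_features_give_identical_outputs(self, model, small_batch):
        batch = dict(small_batch)
        batch["steric"] = np.zeros_like(small_batch["steric"])
        batch["electronic"] = np.zeros_like(small_batch["electronic"])
        # same mask everywhere -> outputs depend only on biases
        mask = np.ones_like(small_batch["mask"])
        batch["mask"] = mask
        out = model.predict(batch)
        assert np.allclose(out, out[0], atol=1e-6)

    def test_rigid_rotation_of_inputs_leaves_prediction_unchanged(
        self, model, tiny_dataset
    ):
        records, _ = tiny_dataset
        rec = records[0]
        base = model.predict(featurize_records([rec], max_atoms=26))[0]
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([
            [np.cos(th), 0, np.sin(th)],
            [0, 1, 0],
            [-np.sin(th), 0, np.cos(th)],
        ])
        import dataclasses

        moved = dataclasses.replace(rec)
        moved.components = {
            role: dataclasses.replace(
                m, coords=m.coords @ rot.T + 2.0, provenance=m.provenance + "@rot"
            )
            for role, m in rec.components.items()
        }
        rotated = model.predict(
            featurize_records([moved], max_atoms=26)
        )[0]
        assert rotated == pytest.approx(base, abs=1e-5)

    def test_role_swap_changes_prediction(self, tiny_trained):
        trained, train, _ = tiny_trained
        rec = train[0]
        base = trained.predict_records([rec])[0]
        import dataclasses

        swapped = dataclasses.replace(rec)
        roles = list(rec.components)
        swapped.components = {
            roles[0]: rec.components[roles[1]],
            roles[1]: rec.components[roles[0]],
        }
        out = trained.predict_records([swapped])[0]
        assert out != pytest.approx(base, abs=1e-6)


class TestInteractionModule:
    def test_matrix_is_symmetric_rank_one(self):
        rng = np.random.default_rng(0)
        mod = _InteractionModule(64, ModelConfig(seed=0), rng)
        v = nn.Tensor(rng.standard_normal((3, 64)).astype(np.float32))
        mod(v, train=False)
        for m in mod.last_matrix:
            assert np.allclose(m, m.T, atol=1e-6)
            assert np.linalg.matrix_rank(m.astype(np.float64), tol=1e-4) <= 1

    def test_outer_product_sign_invariance(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(8)
        assert np.array_equal(np.outer(u, u), np.outer(-u, -u))

    def test_zero_input_yields_bias_only_response(self):
        rng = np.random.default_rng(2)
        mod = _InteractionModule(64, ModelConfig(seed=0), rng)
        v0 = nn.Tensor(np.zeros((2, 64), dtype=np.float32))
        out = mod(v0, train=False)
        assert np.allclose(mod.last_matrix, 0.0)
        assert np.allclose(out.data[0], out.data[1])


class TestGCN:
    def test_permutation_invariance(self, tiny_dataset):
        records, _ = tiny_dataset
        feats = featurize_records(records[:1], graph_kind="baseline")
        cfg = ModelConfig(seed=0)
        gcn = GCN(2, feats["features"].shape[-1], cfg)
        base = gcn.predict(feats)[0]
        # permute the atoms of the first component
        n = int(feats["mask"][0, 0].sum())
        perm = np.random.default_rng(0).permutation(n)
        f2 = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in feats.items()}
        f2["features"][0, 0, :n] = feats["features"][0, 0, perm]
        f2["adjacency"][0, 0, :n, :n] = feats["adjacency"][0, 0][np.ix_(perm, perm)]
        out = gcn.predict(f2)[0]
        assert out == pytest.approx(base, abs=1e-5)

    def test_single_node_graph_pools_to_node_transform(self):
        cfg = ModelConfig(seed=0)
        gcn = GCN(1, 4, cfg)
        feats = {
            "features": np.ones((1, 1, 1, 4), dtype=np.float32),
            "adjacency": np.zeros((1, 1, 1, 1), dtype=np.float32),
            "mask": np.ones((1, 1, 1), dtype=bool),
        }
        out = gcn.predict(feats)
        assert out.shape == (1,) and np.isfinite(out[0])

    def test_deterministic(self, tiny_dataset):
        records, _ = tiny_dataset
        feats = featurize_records(records[:2], graph_kind="baseline")
        cfg = ModelConfig(seed=3)
        a = GCN(2, feats["features"].shape[-1], cfg).predict(feats)
        b = GCN(2, feats["features"].shape[-1], cfg).predict(feats)
        assert np.array_equal(a, b)

    def test_no_attention_capability(self, tiny_dataset):
        records, _ = tiny_dataset
        feats = featurize_records(records[:1], graph_kind="baseline")
        gcn = GCN(2, feats["features"].shape[-1], ModelConfig(seed=0))
        with pytest.raises(CapabilityError):
            gcn.attention_weights(feats)


class TestFeaturize:
    def test_reaction_tensor_shapes_and_role_order(self, tiny_dataset):
        records, _ = tiny_dataset
        feats = featurize_records(records[:3])
        B, m, A = feats["mask"].shape
        assert (B, m) == (3, 2)
        assert feats["roles"] == records[0].roles
        assert feats["steric"].shape == (3, 2, A, 10, 20)
        assert feats["electronic"].shape == (3, 2, A, 7, 7, 7)

    def test_slice_features_consistent(self, small_batch, model):
        idx = np.array([2, 0])
        out = model.predict(slice_features(small_batch, idx))
        full = model.predict(small_batch)
        assert np.allclose(out, full[idx], atol=1e-6)
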