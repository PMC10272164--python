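import numpy as np
import pytest

from semgnn.errors import ValidationError
from semgnn.mignn import ModelConfig
from semgnn.training import (
    EvalReport,
    SplitSpec,
    component_holdout_split,
    evaluate,
    load_model,
    murcko_group,
    random_split,
    run_trials,
    save_model,
    split_records,
    train_model,
)


class TestRandomSplit:
    def test_sizes(self, tiny_dataset):
        records, _ = tiny_dataset
        train, test = random_split(records[:80], 0.7, seed=0)
        assert (len(train), len(test)) == (56, 24)

    def test_same_seed_same_membership(self, tiny_dataset):
        records, _ = tiny_dataset
        a = random_split(records, 0.7, seed=5)
        b = random_split(records, 0.7, seed=5)
        assert [id(r) for r in a[0]] == [id(r) for r in b[0]]

    def test_different_seeds_differ(self, tiny_dataset):
        records, _ = tiny_dataset
        a = random_split(records, 0.7, seed=0)
        b = random_split(records, 0.7, seed=1)
        assert [id(r) for r in a[0]] != [id(r) for r in b[0]]

    def test_too_few_records(self, tiny_dataset):
        records, _ = tiny_dataset
        with pytest.raises(ValidationError):
            random_split(records[:1], 0.7, seed=0)


class TestComponentHoldout:
    def test_test_partition_collects_all_uses(self, tiny_dataset):
        records, _ = tiny_dataset
        smiles = records[0].components["aryl_halide"].provenance
        k = sum(
            1 for r in records
            if r.components["aryl_halide"].provenance == smiles
        )
        train, test = component_holdout_split(records, "aryl_halide", [smiles])
        assert len(test) == k
        assert all(
            r.components["aryl_halide"].provenance != smiles for r in train
        )

    def test_unknown_held_id(self, tiny_dataset):
        records, _ = tiny_dataset
        with pytest.raises(ValidationError, match="not present"):
            component_holdout_split(records, "aryl_halide", ["c1ccccc1CCC"])

    def test_holding_everything_empties_train(self, tiny_dataset):
        records, _ = tiny_dataset
        all_ids = sorted(
            {r.components["aryl_halide"].provenance for r in records}
        )
        with pytest.raises(ValidationError, match="empties"):
            component_holdout_split(records, "aryl_halide", all_ids)

    def test_murcko_grouping_key(self):
        assert murcko_group("Clc1ccc(C)cc1") == murcko_group("Clc1ccccc1")

    def test_split_records_dispatch(self, tiny_dataset):
        records, _ = tiny_dataset
        spec = SplitSpec(mode="random", ratio=0.5, seed=0)
        train, test = split_records(records, spec)
        assert len(train) + len(test) == len(records)


class TestEvaluateArithmetic:
    @staticmethod
    def _stub(predictions):
        class StubModel:
            def predict(self, feats):
                return np.asarray(predictions, dtype=np.float64)[feats["__idx"]]

        class StubTrained:
            model = StubModel()
            target_mean = 0.0
            target_std = 1.0
            n_train = 0

            def featurize(self, records):
                return {
                    "targets": np.array([r for r in records], dtype=float),
                    "__idx": np.arange(len(records)),
                }

            def predict_features(self, feats):
                return self.model.predict(feats)

        return StubTrained()

    def test_hand_computed_three_point_case(self):
        trained = self._stub([10.0, 50.0, 90.0])
        rep = evaluate(trained, [0.0, 50.0, 100.0])
        assert rep.rmse == pytest.approx(np.sqrt(200.0 / 3.0), abs=1e-9)

    def test_perfect_predictions(self):
        trained = self._stub([1.0, 2.0, 3.0])
        rep = evaluate(trained, [1.0, 2.0, 3.0])
        assert rep.rmse == 0.0 and rep.r2 == 1.0

    def test_mean_prediction_gives_zero_r2(self):
        trained = self._stub([50.0, 50.0])
        rep = evaluate(trained, [0.0, 100.0])
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_targets_give_nan_r2(self):
        trained = self._stub([5.0, 5.0])
        rep = evaluate(trained, [5.0, 5.0])
        assert np.isnan(rep.r2)

    def test_rmse_never_improves_under_added_noise(self):
        # corrupting predictions with noise cannot reduce expected RMSE
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 100, 50)
        pred = y + rng.normal(0, 3, 50)
        base = np.sqrt(np.mean((pred - y) ** 2))
        worse = 0
        for _ in range(100):
            noisy = pred + rng.normal(0, 5, 50)
            if np.sqrt(np.mean((noisy - y) ** 2)) >= base:
                worse += 1
        assert worse >= 95


class TestTrainModel:
    def test_constant_target_is_fit(self, tiny_dataset):
        records, _ = tiny_dataset
        import dataclasses

        const = [dataclasses.replace(r, target=42.0) for r in records[:24]]
        cfg = ModelConfig(epochs=25, batch_size=12, seed=0, learning_rate=3e-3)
        trained = train_model(const, val_fraction=0.25, cfg=cfg)
        assert trained.history.val_rmse.iloc[-1] < 1.0

    def test_zero_learning_rate_changes_nothing(self, tiny_dataset):
        records, _ = tiny_dataset
        cfg = ModelConfig(epochs=2, batch_size=16, seed=0, learning_rate=0.0)
        trained = train_model(records[:16], val_fraction=0.0, cfg=cfg)
        ref = ModelConfig(epochs=2, batch_size=16, seed=0)
        from semgnn.mignn import MIGNN

        fresh = MIGNN(2, trained.max_atoms, ref)
        for a, b in zip(trained.model.parameters(), fresh.parameters()):
            assert np.array_equal(a.data, b.data)
        losses = trained.history.train_loss.to_numpy()
        assert losses[0] == pytest.approx(losses[-1], rel=1e-5)

    def test_seeded_training_reproducible(self, tiny_dataset):
        records, _ = tiny_dataset
        cfg = ModelConfig(epochs=2, batch_size=16, seed=0, learning_rate=1e-3)
        a = train_model(records[:20], val_fraction=0.1, cfg=cfg)
        b = train_model(records[:20], val_fraction=0.1, cfg=cfg)
        assert a.history.train_loss.iloc[-1] == pytest.approx(
            b.history.train_loss.iloc[-1], abs=1e-6
        )

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            train_model([], cfg=ModelConfig(epochs=1))


class TestRunTrials:
    def test_aggregation(self, tiny_dataset):
        records, _ = tiny_dataset
        cfg = ModelConfig(epochs=2, batch_size=24, seed=0)
        spec = SplitSpec(mode="random", ratio=0.75, seed=0)
        rep = run_trials(records[:48], spec, cfg, n_trials=2)
        assert len(rep.trials) == 2
        assert rep.rmse == pytest.approx(
            np.mean([t["rmse"] for t in rep.trials])
        )
        assert rep.rmse_std >= 0.0

    def test_single_trial_has_zero_std(self):
        rep = EvalReport(r2=0.5, rmse=3.0, n_train=10, n_test=5,
                         trials=[{"rmse": 3.0, "r2": 0.5}])
        assert rep.rmse_std == 0.0
        assert rep.rmse_mean == 3.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, tiny_trained):
        trained, _, test = tiny_trained
        path = tmp_path / "model.npz"
        save_model(trained, str(path))
        back = load_model(str(path))
        a = trained.predict_records(test[:4])
        b = back.predict_records(test[:4])
        assert np.allclose(a, b, atol=1e-6)
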