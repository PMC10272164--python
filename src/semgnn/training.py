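"""Data splitting, training loops and multi-trial evaluation statistics.

Targets are z-scored on the training partition only; all reported errors
are back-transformed to raw target units (yield % or kcal/mol).  The
component-holdout split withholds every reaction that uses any of the held
component structures in a given role, the standard extrapolation probe for
reaction datasets; grouping components by Bemis-Murcko scaffold is
available as a helper for scaffold-level holdouts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .chemio import ReactionRecord
from .electronic import ElectronicConfig
from .errors import ValidationError
from .mignn import GCN, MIGNN, ModelConfig, featurize_records, slice_features
from .steric import StericConfig

logger = logging.getLogger("semgnn.training")

EVAL_CHUNK = 128


@dataclass
class SplitSpec:
    """Random-ratio or component-holdout split definition."""

    mode: str = "random"
    ratio: float = 0.7
    role: str | None = None
    held_ids: list[str] = field(default_factory=list)
    seed: int = 0


@dataclass
class EvalReport:
    """Regression metrics, raw target units; optionally aggregated trials."""

    r2: float
    rmse: float
    n_train: int
    n_test: int
    trials: list[dict] = field(default_factory=list)

    @property
    def rmse_mean(self) -> float:
        return float(np.mean([t["rmse"] for t in self.trials])) if self.trials else self.rmse

    @property
    def rmse_std(self) -> float:
        vals = [t["rmse"] for t in self.trials]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def r2_mean(self) -> float:
        return float(np.mean([t["r2"] for t in self.trials])) if self.trials else self.r2


def random_split(
    records: list[ReactionRecord], ratio: float, seed: int
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Shuffled ratio split; train size is round(ratio * n)."""
    n = len(records)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    if not (0.0 < ratio < 1.0):
        raise ValidationError("ratio must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = min(max(int(round(ratio * n)), 1), n - 1)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def component_holdout_split(
    records: list[ReactionRecord], role: str, held_ids: list[str]
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Extrapolative split: hold out whole component structures.

    ``held_ids`` are component identities (the provenance strings, i.e.
    SMILES) for ``role``.  Every reaction using a held component lands in
    the test set; a zero-leakage assertion runs before returning.
    """
    if not held_ids:
        raise ValidationError("held_ids must be nonempty")
    present = {rec.components[role].provenance for rec in records}
    missing = set(held_ids) - present
    if missing:
        raise ValidationError(f"held ids not present in dataset: {sorted(missing)}")
    held = set(held_ids)
    train = [r for r in records if r.components[role].provenance not in held]
    test = [r for r in records if r.components[role].provenance in held]
    if not train or not test:
        raise ValidationError("holdout empties the train or test partition")
    assert not any(r.components[role].provenance in held for r in train), "leakage"
    return train, test


def murcko_group(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES, the default component grouping key."""
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def split_records(
    records: list[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    if spec.mode == "random":
        return random_split(records, spec.ratio, spec.seed)
    if spec.mode == "component_holdout":
        if spec.role is None:
            raise ValidationError("component_holdout requires a role")
        return component_holdout_split(records, spec.role, spec.held_ids)
    raise ValidationError(f"unknown split mode {spec.mode!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted model plus everything needed to apply it to new records."""

    model: object
    model_kind: str
    graph_kind: str
    cfg: ModelConfig
    steric_cfg: StericConfig
    electronic_cfg: ElectronicConfig
    max_atoms: int
    roles: list[str]
    target_mean: float
    target_std: float
    history: pd.DataFrame
    n_train: int = 0

    def featurize(self, records: list[ReactionRecord]) -> dict:
        # predictions are padding-invariant, so the pad width may grow for
        # records bigger than anything seen in training
        width = max(
            self.max_atoms,
            max(m.n_atoms for r in records for m in r.molecules),
        )
        feats = featurize_records(
            records, self.steric_cfg, self.electronic_cfg,
            max_atoms=width, graph_kind=self.graph_kind,
        )
        if feats["roles"] != self.roles:
            raise ValidationError("record role order differs from training schema")
        return feats

    def predict_features(self, feats: dict) -> np.ndarray:
        """Predictions in raw target units, chunked evaluation."""
        n = len(feats["targets"])
        preds = np.empty(n)
        for lo in range(0, n, EVAL_CHUNK):
            idx = np.arange(lo, min(lo + EVAL_CHUNK, n))
            z = self.model.predict(slice_features(feats, idx))
            preds[idx] = z * self.target_std + self.target_mean
        return preds

    def predict_records(self, records: list[ReactionRecord]) -> np.ndarray:
        return self.predict_features(self.featurize(records))


def train_model(
    train_records: list[ReactionRecord],
    val_fraction: float = 0.1,
    cfg: ModelConfig | None = None,
    model_kind: str = "mignn",
    graph_kind: str = "semg",
    steric_cfg: StericConfig | None = None,
    electronic_cfg: ElectronicConfig | None = None,
    max_atoms: int | None = None,
) -> TrainedModel:
    """Fit a model with Adam on mean-squared error of the z-scored target.

    All randomness (weight init, batch shuffling, validation carve-out)
    flows from ``cfg.seed``.  Divergence (non-finite loss) aborts with
    diagnostics.  Returns the fitted bundle with a per-epoch history
    (train loss in z-units, validation RMSE in raw units).
    """
    if not train_records:
        raise ValidationError("empty training set")
    cfg = cfg or ModelConfig()
    steric_cfg = steric_cfg or StericConfig()
    electronic_cfg = electronic_cfg or ElectronicConfig()
    feats = featurize_records(
        train_records, steric_cfg, electronic_cfg,
        max_atoms=max_atoms, graph_kind=graph_kind,
    )
    n = len(train_records)
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(fit_idx) == 0:
        raise ValidationError("validation fraction leaves no training data")
    y = feats["targets"]
    mu = float(y[fit_idx].mean())
    sd = float(y[fit_idx].std())
    sd = sd if sd > 1e-12 else 1.0
    z = ((y - mu) / sd).astype(np.float64)

    m = len(feats["roles"])
    if model_kind == "mignn":
        model = MIGNN(m, feats["max_atoms"], cfg)
    elif model_kind == "gcn":
        if graph_kind == "semg":
            flen = int(
                np.prod(feats["steric"].shape[3:]) + np.prod(feats["electronic"].shape[3:])
            )
        else:
            flen = feats["features"].shape[-1]
        model = GCN(m, flen, cfg)
        model._feature_len = flen
    else:
        raise ValidationError(f"unknown model_kind {model_kind!r}")

    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    bundle = TrainedModel(
        model, model_kind, graph_kind, cfg, steric_cfg, electronic_cfg,
        feats["max_atoms"], feats["roles"], mu, sd, pd.DataFrame(), n_train=n,
    )
    decay_at = int(0.7 * cfg.epochs)
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "step" and epoch == decay_at and epoch > 0:
            opt.lr = cfg.learning_rate * 0.3
        order = rng.permutation(fit_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            batch = slice_features(feats, idx)
            pred = model.forward(batch, train=True)
            resid = pred - nn.Tensor(z[idx].astype(nn.DEFAULT_DTYPE))
            loss = (resid * resid).mean()
            if not np.isfinite(loss.data):
                raise ValidationError(
                    f"training diverged at epoch {epoch} (loss={loss.data})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(val_idx):
            val_pred = bundle.predict_features(slice_features(feats, val_idx))
            row["val_rmse"] = float(np.sqrt(np.mean((val_pred - y[val_idx]) ** 2)))
        history.append(row)
    bundle.history = pd.DataFrame(history)
    return bundle


def evaluate(trained: TrainedModel, test_records: list[ReactionRecord]) -> EvalReport:
    """RMSE (raw units) and R^2 = 1 - SS_res/SS_tot on a test partition."""
    if not test_records:
        raise ValidationError("empty test set")
    feats = trained.featurize(test_records)
    y = feats["targets"]
    pred = trained.predict_features(feats)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-12:
        logger.warning("zero-variance test targets: R^2 undefined (NaN)")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(((pred - y) ** 2).sum()) / ss_tot
    return EvalReport(r2, rmse, n_train=trained.n_train, n_test=len(y))


def run_trials(
    records: list[ReactionRecord],
    spec: SplitSpec,
    cfg: ModelConfig | None = None,
    n_trials: int = 10,
    **train_kwargs,
) -> EvalReport:
    """Repeat split + train + evaluate; trial t uses split/init seed base+t.

    Aggregation follows the mean +/- sample standard deviation convention.
    """
    cfg = cfg or ModelConfig()
    train_kwargs.setdefault(
        "max_atoms", max(m.n_atoms for r in records for m in r.molecules)
    )
    trials = []
    for t in range(n_trials):
        tspec = SplitSpec(spec.mode, spec.ratio, spec.role, spec.held_ids,
                          seed=spec.seed + t)
        tcfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + t})
        train, test = split_records(records, tspec)
        trained = train_model(train, cfg=tcfg, **train_kwargs)
        rep = evaluate(trained, test)
        trials.append({"trial": t, "rmse": rep.rmse, "r2": rep.r2,
                       "n_train": len(train), "n_test": len(test)})
    agg = EvalReport(
        r2=float(np.mean([t["r2"] for t in trials])),
        rmse=float(np.mean([t["rmse"] for t in trials])),
        n_train=trials[0]["n_train"],
        n_test=trials[0]["n_test"],
        trials=trials,
    )
    return agg


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(trained: TrainedModel, path: str) -> None:
    """Single-file .npz archive with parameters and embedded config JSON."""
    meta = {
        "model_kind": trained.model_kind,
        "graph_kind": trained.graph_kind,
        "cfg": trained.cfg.__dict__,
        "max_atoms": trained.max_atoms,
        "roles": trained.roles,
        "target_mean": trained.target_mean,
        "target_std": trained.target_std,
        "steric": {"radius": trained.steric_cfg.radius,
                   "n_polar": trained.steric_cfg.n_polar},
        "electronic": {"backend": trained.electronic_cfg.backend},
        "feature_len": getattr(trained.model, "_feature_len", None),
    }
    arrays = trained.model.state_arrays()
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path: str) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg = ModelConfig(**meta["cfg"])
    m = len(meta["roles"])
    if meta["model_kind"] == "mignn":
        model = MIGNN(m, meta["max_atoms"], cfg)
    else:
        flen = meta.get("feature_len") or 0
        model = GCN(m, int(flen), cfg)
    model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return TrainedModel(
        model, meta["model_kind"], meta["graph_kind"], cfg,
        StericConfig(radius=meta["steric"]["radius"], n_polar=meta["steric"]["n_polar"]),
        ElectronicConfig(backend=meta["electronic"]["backend"]),
        meta["max_atoms"], list(meta["roles"]),
        meta["target_mean"], meta["target_std"], pd.DataFrame(),
    )
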