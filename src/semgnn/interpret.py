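"""Atom-level model interpretation.

Two complementary probes of a trained model:

* **Encoding elimination** — zero one atom's steric or electronic encoding
  and record the change of the prediction (perturbed minus original).
  Because the two encodings enter through separate channels, the
  per-channel perturbation profiles indicate whether the model's decision
  leans on steric or electronic information.  The probe is intuitive, not
  causal, and perturbations are not additive across channels.
* **Attention weights** — the atom-attention layer's weights, normalized
  per molecule, locate the atoms the model attends to.

Both probes are pure: they operate on copies of the featurized tensors and
never mutate stored encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemio import ReactionRecord
from .errors import ValidationError
from .training import TrainedModel

CHANNELS = ("steric", "electronic")


@dataclass
class PerturbationResult:
    """Per-(reaction, atom, channel) prediction changes for one molecule."""

    molecule: str
    role: str
    n_atoms: int
    deltas: pd.DataFrame  # columns: reaction, atom, element, channel, delta
    histogram_bins: np.ndarray = field(default_factory=lambda: np.array([]))

    def channel_mean_abs(self, channel: str) -> float:
        sel = self.deltas[self.deltas.channel == channel]
        return float(sel.delta.abs().mean())

    def histogram(self, channel: str, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        sel = self.deltas[self.deltas.channel == channel]
        return np.histogram(sel.delta.abs(), bins=bins)


def _role_index(feats: dict, role: str) -> int:
    try:
        return feats["roles"].index(role)
    except ValueError as exc:
        raise ValidationError(f"role {role!r} not in schema {feats['roles']}") from exc


def eliminate_encoding(
    trained: TrainedModel,
    record: ReactionRecord,
    role: str,
    atom_index: int,
    channel: str,
) -> float:
    """Prediction change when one atom's channel encoding is zeroed.

    Returns perturbed minus original prediction, in raw target units.  The
    record and its stored encodings are untouched.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"channel must be one of {CHANNELS}")
    feats = trained.featurize([record])
    r = _role_index(feats, role)
    if not (0 <= atom_index < record.components[role].n_atoms):
        raise IndexError(
            f"atom index {atom_index} out of range for role {role!r}"
        )
    original = trained.predict_features(feats)[0]
    perturbed = dict(feats)
    arr = feats[channel].copy()
    arr[0, r, atom_index] = 0.0
    perturbed[channel] = arr
    return float(trained.predict_features(perturbed)[0] - original)


def perturbation_scan(
    trained: TrainedModel,
    records: list[ReactionRecord],
    role: str,
    batch_size: int = 64,
) -> PerturbationResult:
    """Eliminate every (atom, channel) of one molecule across reactions.

    All records must carry the same molecule in ``role``.  Produces
    n_reactions x n_atoms x 2 perturbations, evaluated in batches of
    perturbed copies for speed.
    """
    if not records:
        raise ValidationError("empty record subset")
    mol = records[0].components[role]
    ident = mol.provenance
    for rec in records:
        if rec.components[role].provenance != ident:
            raise ValidationError(
                f"all records must share the same {role!r} molecule"
            )
    feats = trained.featurize(records)
    r = _role_index(feats, role)
    checksum = {c: feats[c].sum() for c in CHANNELS}
    base = trained.predict_features(feats)
    n_atoms = mol.n_atoms
    rows = []
    for channel in CHANNELS:
        for atom in range(n_atoms):
            perturbed = dict(feats)
            arr = feats[channel].copy()
            arr[:, r, atom] = 0.0
            perturbed[channel] = arr
            pred = trained.predict_features(perturbed)
            for k in range(len(records)):
                rows.append(
                    {
                        "reaction": k,
                        "atom": atom,
                        "element": mol.symbols[atom],
                        "channel": channel,
                        "delta": float(pred[k] - base[k]),
                    }
                )
    for c in CHANNELS:
        assert feats[c].sum() == checksum[c], "perturbation mutated stored encodings"
    return PerturbationResult(ident, role, n_atoms, pd.DataFrame(rows))


def attention_weights(
    trained: TrainedModel,
    record: ReactionRecord,
    channel: str = "steric",
    layer: int = -1,
) -> dict[str, np.ndarray]:
    """Normalized per-atom attention weights of one reaction, by role.

    Weights are taken from the requested atom-attention layer (default:
    last), averaged over each molecule's real query atoms and normalized
    to sum to 1 over the molecule's real atoms; padded slots are 0.
    Models without attention layers (the GCN control) raise a capability
    error.
    """
    feats = trained.featurize([record])
    w = trained.model.attention_weights(feats, channel=channel, layer=layer)
    out = {}
    for r, role in enumerate(feats["roles"]):
        n = record.components[role].n_atoms
        out[role] = w[0, r, :n]
    return out


def scan_to_csv(result: PerturbationResult, path: str) -> None:
    """Write a perturbation scan as a flat CSV (one row per perturbation)."""
    df = result.deltas.copy()
    df.insert(0, "molecule", result.molecule)
    df.insert(1, "role", result.role)
    df.to_csv(path, index=False)
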