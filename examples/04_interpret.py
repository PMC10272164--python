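"""Atom-level interpretation: encoding elimination and attention weights.

After training on steric-only planted data, zeroing an atom's *steric*
encoding should change predictions much more than zeroing its electronic
encoding — the perturbation scan recovers which channel carries the
signal.  Attention weights locate the atoms the model attends to.
Runs in about two minutes on one CPU core.
"""

from semgnn import ModelConfig, SyntheticSpec, build_library, generate_dataset
from semgnn import attention_weights, perturbation_scan, random_split, train_model

library = build_library(0)
spec = SyntheticSpec(n_reactions=200, effect_mode="steric_only", noise_sd=2.0, seed=0)
records, _ = generate_dataset(spec, library)
train, _ = random_split(records, 0.75, seed=0)
trained = train_model(
    train, cfg=ModelConfig(epochs=25, batch_size=32, seed=0, learning_rate=3e-3)
)

probe = "Clc1ccc(C(C)(C)C)cc1"  # the bulky tert-butyl aryl chloride
subset = [r for r in records
          if r.components["aryl_halide"].provenance == probe][:12]
scan = perturbation_scan(trained, subset, "aryl_halide")
s, e = scan.channel_mean_abs("steric"), scan.channel_mean_abs("electronic")
print(f"{len(scan.deltas)} perturbations on {probe}")
print(f"mean |delta| steric     = {s:.3f}% of yield")
print(f"mean |delta| electronic = {e:.3f}% of yield")
print(f"channel dominance ratio = {s / e:.1f}x "
      "(>1: the model leans on the steric channel, as planted)")

weights = attention_weights(trained, subset[0], channel="steric")
mol = subset[0].components["aryl_halide"]
top = sorted(enumerate(weights["aryl_halide"]), key=lambda kv: -kv[1])[:3]
print("highest-attention atoms:",
      ", ".join(f"{mol.symbols[i]}{i} ({w:.2f})" for i, w in top))
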