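"""Train the interaction GNN on a synthetic dataset with a planted
steric response and evaluate on a held-out split.

The generator combines substituted aryl halides and amines and plants a
target that depends only on the steric encodings around each component's
reactive atom (plus Gaussian noise, sd 2 on a ~13-sd yield scale), so
held-out R^2 close to 1 means the model recovered the planted structure.
Runs in about a minute on one CPU core.
"""

from semgnn import ModelConfig, SyntheticSpec, build_library, generate_dataset
from semgnn import evaluate, random_split, train_model

library = build_library(0)
spec = SyntheticSpec(n_reactions=240, effect_mode="steric_only",
                     noise_sd=2.0, seed=0)
records, ledger = generate_dataset(spec, library)
print(f"{len(records)} reactions, target sd {ledger.target.std():.1f}%")

train, test = random_split(records, ratio=0.7, seed=0)
cfg = ModelConfig(epochs=40, batch_size=32, seed=0, learning_rate=3e-3,
                  lr_schedule="step")
trained = train_model(train, val_fraction=0.1, cfg=cfg)
print(trained.history.tail(3).to_string(index=False))

report = evaluate(trained, test)
print(f"held-out R^2 = {report.r2:.3f}, RMSE = {report.rmse:.2f}% "
      f"(noise floor ~{spec.noise_sd:.0f}%)")
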