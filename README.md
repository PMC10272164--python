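# semgnn

Reaction performance prediction from chemistry-aware molecular graphs.

`semgnn` predicts scalar reaction outcomes — yield (%) or
enantioselectivity expressed as ΔΔG‡ (kcal/mol) — for multi-component
reactions (substrate + coupling partner + catalyst + ...), for people who
model structure–performance relationships in synthetic chemistry:
high-throughput experimentation groups, catalysis labs screening
candidate ligands or chiral phosphoric acids, and method developers who
need an extrapolation-capable, atom-interpretable baseline.

## The model

Every component molecule is encoded as a **steric- and
electronics-embedded molecular graph (SEMG)**: the ordinary molecular
graph in which each atom *i* carries

* a **steric map** `S_i ∈ R^{10×20}` — from a sphere of radius R = 10 Å
  centered on atom *i*, the equirectangular grid over (θ, φ) records
  `S_i[θ,φ] = R − d_vdW(θ,φ)`, the gap between the reference sphere and
  the farthest point of the molecular van der Waals surface along each
  ray (a spherical projection of the molecular stereostructure); and
* an **electronic tensor** `E_i ∈ R^{7×7×7}` — the electron density
  ρ(r) (e/Bohr³) evaluated on a 7×7×7 grid spanning the cube of side
  2·r_vdW(i) centered on atom *i* (promolecule density by default, ab
  initio density via an optional backend).

Geometries are standardized (center of gravity → origin, nearest atom →
+z, farthest atom → yz plane, proper rotations only), so the encodings
are rigid-motion invariant yet distinguish enantiomers.

The **molecular-interaction graph neural network (MIGNN)** processes the
two channels separately — atom attention, linear/batch-norm/tanh layers,
per-atom convolution, pooling over atoms, concatenation of the *m*
components in role order — into reaction vectors `v_s, v_e`.  Each
channel's vector is compressed to a representation `u` whose outer
product `M = u uᵀ` (symmetric, rank 1) lets every component's information
multiply every other's; convolving and flattening `M` yields interaction
vectors.  The four blocks `[v_s, v_e, i_s, i_e]` pass one attention layer
and three linear layers to the prediction.  A graph-convolution control
(GCN, no attention, no interaction module) and a classic hand-featured
baseline graph support four-way ablations.

Training minimizes MSE on z-scored targets with Adam; evaluation reports
RMSE (raw units) and R², with random or component-holdout
(scaffold-style extrapolation) splits and repeated-trial aggregation.
Trained models are interpretable at atomic resolution by **encoding
elimination** (zero one atom's steric or electronic encoding, record the
prediction change) and by attention weights.

The neural-network layer runs on a compact NumPy reverse-mode autodiff
engine built into the package (`semgnn.nn`) — no GPU or deep-learning
framework required; everything trains on one CPU core.

## Worked example

```python
from semgnn import (ModelConfig, SyntheticSpec, build_library,
                    generate_dataset, evaluate, random_split, train_model)

library = build_library(0)                       # 24 aryl halides x 24 amines
spec = SyntheticSpec(n_reactions=240, effect_mode="steric_only",
                     noise_sd=2.0, seed=0)
records, ledger = generate_dataset(spec, library)

train, test = random_split(records, ratio=0.7, seed=0)
cfg = ModelConfig(epochs=40, batch_size=32, seed=0, learning_rate=3e-3,
                  lr_schedule="step")
trained = train_model(train, val_fraction=0.1, cfg=cfg)
report = evaluate(trained, test)
print(report.r2, report.rmse)
```

Running `python examples/03_train_synthetic.py` (this script, with its
printed epilogue) produces:

```
240 reactions, target sd 12.9%
held-out R^2 = 0.937, RMSE = 3.47% (noise floor ~2%)
```

The dataset plants a target that depends only on the steric encodings
around each component's reactive atom, with 2% Gaussian noise on a
~13%-spread yield scale; R² near 1 means the network recovered the
planted structure from the encodings, and the RMSE approaches the noise
floor as training lengthens.  `examples/04_interpret.py` continues this
workflow: a perturbation scan of the bulky tert-butyl aryl chloride
attributes several times more |Δprediction| to the steric channel than
to the electronic one — the planted ground truth.

The other example scripts show single-molecule encoding
(`01_encode_molecule.py`) and frame invariance plus chirality
preservation (`02_frame_invariance.py`).  A thin CLI covers the same
pipeline from the shell: `semgnn synth | encode | split | train |
evaluate | interpret` (see `semgnn --help`).

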