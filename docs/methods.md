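# Methods

This note documents the models and procedures implemented in `semgnn`,
the choices made where the design was genuinely open, and what the
built-in synthetic studies do and do not demonstrate.

## Problem setting

The package predicts a scalar reaction performance — yield in percent, or
an enantioselectivity expressed as the differential activation free
energy ΔΔG‡ in kcal/mol — from the structures of the reaction components
(substrates, catalyst, additives).  Each component molecule is encoded as
a molecular graph whose nodes carry two dense descriptions of the atom's
local environment: a steric distance map and an electron-density grid
(together, a steric- and electronics-embedded molecular graph, SEMG).  A
two-channel neural network with an explicit molecular-interaction module
(MIGNN) maps the ordered set of component graphs to the prediction.

## Geometry

Conformers come from RDKit's ETKDG distance-geometry method with a fixed
seed (one conformer per molecule; no ensemble averaging) and are relaxed
with MMFF94.  An external tight-binding optimizer can be plugged in
through an XYZ round-trip contract (`optimize_geometry(...,
backend="external_xtb")`); results with the force field differ slightly
from tight-binding geometries, but every downstream stage is geometry-
source-agnostic.

Before encoding, every molecule is brought into a canonical pose so the
encodings cannot depend on the input frame: the mass-weighted center of
gravity moves to the origin; the atom closest to it is rotated onto the
+z axis; the atom furthest from it is rotated into the yz plane, y ≥ 0.
Both rotations are proper (det +1), composed from explicit axis-angle
steps, so mirror images stay distinct — necessary for any
enantioselectivity task.  Open details decided here: "center of gravity"
is read as the mass-weighted center (not the geometric centroid); ties in
the key-atom selection (equal distances within 1e-6 Å) break to the
lowest atom index; a single atom gets translation only; if the furthest
atom lies on the z axis the azimuthal step is skipped (all azimuths are
equivalent).

## Steric encoding

For each atom a sphere of radius R = 10 Å is centered on it and the
angular domain is discretized on an equirectangular grid: polar angle θ
into N = 10 bins, azimuth φ into 2N = 20 bins, both sampled at bin
centers (offset ½ avoids the degenerate poles and the φ seam).  Along
each bin-center ray the entry is R minus the distance to the *outermost*
intersection with any atom's van der Waals sphere (Bondi radii; the table
is overridable).  Outermost, because nearer intersections are occluded
from the sphere looking inward; a ray that hits nothing contributes R.
Intersections are the exact quadratic ray–sphere roots, not sampled.
Entries are clamped to [0, R]; a molecule poking out of the sphere logs a
warning.  R = 10 Å comfortably covers the molecules used here (the
radius is a config knob for larger systems).

## Electronic encoding

For each atom a cube with side equal to the atom's vdW diameter is
partitioned into 7 × 7 × 7 cells and the electron density is evaluated at
the cell centers (e/Bohr³), in the standardized global frame.  The
default density backend is a promolecule model: a sum of spherical atomic
densities ρ_a(r) = c_a·exp(−r/λ_a), with λ_a from Slater-rule valence
exponents and c_a normalized so each atom integrates to its electron
count.  This is not an ab initio density; it carries element identity and
local environment (neighbor tails overlap the cube) at zero cost, which
is the information the encoding needs.  A quantum-chemistry backend
(`external_qm_density`) is a documented contract with identical units and
grid conventions, so DFT densities are drop-in if PySCF is installed.

## Graphs

A SEMG is the plain molecular graph (atoms as nodes, bonds as edges,
orders dropped, no edge features) with the 10×20 map and 7×7×7 tensor on
every node, explicit hydrogens included.  The baseline control graph
carries classic hand-picked node features only: one-hot element over a
pinned vocabulary (with an "other" slot), atomic number, degree, formal
charge, aromatic flag, and rule-based H-bond donor/acceptor flags.
Batches are zero-padded to a dataset-level `max_atoms` with a validity
mask; padded nodes are excluded from attention, batch statistics and
pooling everywhere downstream.

## Model

Both channels (steric, electronic) are processed by identically shaped
but independently parameterized stacks:

1. `atom_attention` layers of masked scaled-dot-product self-attention
   over each molecule's atoms, on the flattened per-atom encoding.
   Attention was chosen over neighborhood aggregation deliberately: the
   graph-convolution control exists separately, and the attention matrix
   is what the interpretation reads.  This is the main architectural
   interpretation risk and is therefore isolated behind one module.
2. `linear_depth` linear layers, each followed by batch normalization
   (statistics over real atoms only) and tanh; the last layer maps back
   to the encoding's spatial grid so convolutions see spatial structure.
3. A per-atom convolution over the grid (2-D, 3×3 for steric; 3-D,
   3×3×3 for electronic), max-pooling over each molecule's real atoms
   (padded slots enter as −1e9), concatenation of the m component
   molecules along the channel axis — this is where role order becomes
   information-bearing — then a strided 3×3 convolution (steric) or a
   2×2×2 spatial max-pool (electronic; this channel gets no second
   convolution) and flattening to the one-dimensional reaction vector.
4. Interaction module: `inter_attention` self-attention layers over a
   tokenized view of the reaction vector, one linear layer down to a
   representation u (16 units), the rank-one interaction matrix
   M = u·uᵀ — every component's information multiplies every other's —
   then three 3×3 convolutions and flattening give the interaction
   vector.  M is symmetric and rank one by construction; u → −u leaves it
   unchanged.
5. Head: the two reaction vectors and the two interaction vectors are
   each projected to a common width, one attention layer weighs the four
   blocks, and three linear layers produce the scalar.

The per-atom convolutions are executed as one dense matrix product per
channel (the small-kernel convolution is a sparse linear map that is
cheaper to materialize than to window, at these sizes); equivalence with
the direct convolution is tested.

The GCN control shares the featurization and replaces the whole
architecture with two symmetric-normalized graph convolutions, masked
mean pooling, concatenation across components and a linear head — no
attention, no interaction module.  The four-way comparison
(baseline/SEMG features × GCN/MIGNN) is available through
`graph_kind`/`model_kind` in `train_model`.

Widths, kernel sizes, token counts and the position of batch norm
relative to tanh are not pinned by the architecture's published
description; the defaults in `ModelConfig` (hidden width 48, 4
convolution channels, key width 16, u-dim 16) were chosen once for
desk-scale CPU training and are all exposed.

## Training and evaluation

Loss is mean squared error on the z-scored target (statistics from the
training partition only; all reported errors are back-transformed to raw
units).  Optimizer is Adam, default lr 1e-3 (the synthetic studies use
3e-3), batch size 50, float32 network arithmetic.  All randomness —
weight init, batch shuffling, validation carve-out — flows from one seed;
repeated-trial protocols move the split seed and the init seed together
and report mean ± sample standard deviation.  RMSE and R² = 1 −
SS_res/SS_tot are computed in raw target units; zero-variance test
targets make R² undefined (reported as NaN with a warning).

Splits: shuffled ratio splits, and component holdout — every reaction
using a held component structure in a given role goes to the test set,
with a zero-leakage assertion.  Components can be grouped by
Bemis–Murcko scaffold (`murcko_group`) before holding out groups; the
grouping function is pluggable because scaffold-family definitions are a
dataset-level choice.

## Interpretation

Encoding elimination zeroes one atom's steric or electronic features in
a copy of the featurized tensors and records the prediction change
(perturbed − original, signed; plots typically take |Δ|).  Perturbations
are not additive across channels, and the probe is an intuition aid, not
a causal attribution.  Attention weights are read from a selectable
atom-attention layer (default: last), averaged over each molecule's real
query atoms and normalized to sum to one over real atoms; padded atoms
get exactly zero.

## Synthetic data generator

The generator emulates the shape of high-throughput coupling datasets:
two component roles (an aryl-halide-like role and an amine-like role), 24
library molecules per role built from substituted benzenes and pyridines
(methyl, tert-butyl, methoxy, fluoro, cyano, trifluoromethyl,
thiomethyl variants; each role contains a parent/tert-butyl steric probe
pair), one tagged reactive atom per molecule, full-factorial combination
space (576), sampling without replacement.  The planted response reads
the package's *own* encodings — steric term: mean steric-map entry over
the atoms bonded to the reactive atom; electronic term: central-cell
density at the reactive atom — z-scored against the role's library
population, combined linearly (steric-only, electronic-only, mixed) or
with a cross-component product term (interaction mode), plus Gaussian
noise (default sd 2 on a ~13-sd yield scale) and clipping of yields to
[0, 100] (clipping affects ~1% of interaction-mode draws).  Defining the
response on the model's input features makes the noiseless learnability
ceiling exactly R² = 1, so failures separate cleanly into architecture
defects versus encoding defects.

What the generator does *not* emulate: real reaction chemistry
(mechanism, incompatible pairs, heteroscedastic noise, censoring at 0%
yield), larger component counts, or the target distributions of the
published benchmark datasets.  Passing the recovery studies therefore
shows that the pipeline can learn and attribute structure planted in its
encodings at realistic dataset sizes — not that it reproduces published
accuracies on downloaded data.

## Reference studies and problem sizes

`semgnn.experiments.steric_recovery` trains on 500 steric-only reactions
(70/30 split, 50 epochs) and perturbation-scans the bulky probe molecule
over up to 24 of its reactions; recovery is summarized by held-out R²
and the channel-dominance ratio mean|Δ_steric|/mean|Δ_electronic|.
`semgnn.experiments.interaction_benefit` compares the full model against
an interaction-ablated but otherwise identical control on 300
interaction-mode reactions over 5 paired seeds (45 epochs each),
summarized by median held-out RMSE.  Both reference studies use lr 3e-3
with a step schedule (×0.3 after 70% of epochs, applied identically to
every arm) so the compared models are converged rather than
noise-dominated.  The library conformers are treated
as a fixed reagent panel; the experiment seed drives sampling, noise,
splitting and initialization.  These sizes were chosen as what a single
CPU core completes in minutes.

## Numerical choices and edge cases

- Ray–sphere intersections use the analytic quadratic; extents below 0
  are discarded, misses contribute extent 0 (entry R).
- Density tensors validate non-negativity and finiteness; missing
  promolecule parameters raise a configuration error naming the element.
- Batch norm keeps running statistics (momentum 0.1, eps 1e-5) for
  evaluation mode; checkpoints store them alongside weights.
- Max-pooling over atoms substitutes −1e9 for padded slots; gradient
  flows to the (first) argmax.
- Training aborts with diagnostics on a non-finite loss; the forward
  pass raises on NaN at the prediction head.
- Degenerate orientation inputs (single atom, key atom at the center,
  linear molecules) skip undefined rotations instead of raising.

## Known limitations

- The promolecule density has no bonding anisotropy; attribution results
  concerning subtle electronic effects should be re-examined with a QM
  backend.
- The steric map records the outermost vdW intersection; whether the
  original spherical-projection descriptor records nearest or farthest
  surface point is not fully specified in its published description, and
  the choice here is pinned and documented rather than validated against
  the reference implementation.
- Attention is intramolecular only; intermolecular coupling happens only
  through concatenation and the interaction module.
- Single conformer per molecule; conformer-dependent steric maps of
  floppy molecules are noisier than the encoding acknowledges.
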