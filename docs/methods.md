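# Methods

## Overview

`apoflow` generates bound (holo) protein–ligand complex structures, with
per-residue confidence and binding affinity estimates, by conditional flow
matching (CFM) on heavy-atom coordinates in R³. A complex's state at flow
time `t ∈ [0, 1]` is the pair `(x^P, x^L)` of protein and ligand heavy-atom
coordinates. At `t = 0` the state is drawn from a structured prior — the
user-supplied unbound (apo) protein plus a harmonic ligand conformation —
and a learned map transports it to the bound complex at `t = 1`.

## Prior distributions

**Protein.** The apo structure is used directly. During training,
isotropic Gaussian noise `ε ~ N(0, σ)` with `σ = 1e-4 Å` is added to both
the apo input and the holo target coordinates, so the model learns a
distribution around each structure pair rather than a point-to-point map
and does not overfit coordinate noise. At inference no noise is added.

**Ligand.** Initial conformations are drawn from a harmonic prior: the
zero-mean Gaussian whose precision matrix is the bond-graph Laplacian
`L = D − A` (degree minus adjacency, all bonds weight 1), independently
per spatial dimension. Bonded atoms therefore stay at unit-scale
distances while non-bonded atoms decorrelate with graph distance: the
expected squared distance between atoms u and v is `3·R_eff(u, v)`, three
times the effective resistance `L⁺_uu + L⁺_vv − 2 L⁺_uv`. `L` is singular
(one zero eigenvalue per connected fragment, the translation mode), so we
sample eigencoefficients `c_k ~ N(0, 1/λ_k)` only in the strictly positive
eigenspace and fix translations explicitly: each fragment's centroid is
placed at the apo protein's heavy-atom centroid (blind docking default) or
at a user-supplied pocket center. This is the unique well-defined reading
of "Gaussian with precision L" for a singular precision. Bond-type
weighting of `L` would be a natural extension and is not implemented.

## Conditional path and loss

Training pairs `(x0, x1)` combine an independent prior draw with a noised
holo target; the conditional probability path is the straight-line
(conditional optimal transport) interpolation

    x_t = (1 − t)·x0 + t·x1,    t ~ U(0, 1).

The network `v(x_t, t)` is parametrized as an **x1-predictor**: the loss
regresses its output directly against the holo target,

    L = E ‖v(x_t, t) − x1‖²,

reduced as a weighted mean over atoms and spatial dimensions. Ligand atoms
receive weight `ligand_weight` relative to protein atoms inside the mean,
so at weight 1 the loss is the plain mean squared error. The training
default is `ligand_weight = 4`: ligands contribute few atoms relative to
the receptor (often 1–10 vs ~50 in the toy regime) and are the primary
output of docking, so without upweighting their gradient signal is diluted
by the atom-count ratio. The sampler converts the x1-prediction into
motion; a separately-parametrized velocity field is not needed.

Auxiliary heads are trained jointly: a per-residue confidence head against
lDDT labels of the current prediction vs the holo target (mean squared
error, weight 0.5) and an affinity head against the label in pK units
(squared error, weight 0.1, masked when no label exists). The weights
roughly balance the three terms' initial magnitudes and were fixed once.

## Apo–holo coupling filter

Training consumes only apo/holo pairs that pass a structural-compatibility
filter (an unbalanced coupling: candidates are drawn independently and
rejected outside the acceptance set). The apo Cα trace is aligned onto the
holo trace by weighted Kabsch superposition with ligand-proximity weights
`w_i = exp(−d_i / 5 Å)` (d_i = distance of residue i's Cα to the nearest
crystal-ligand heavy atom, weights normalized), concentrating the fit on
the binding pocket; the exponential form is a smooth, scale-interpretable
choice. The pair is kept iff

    TM ≥ 0.7   and   Cα-RMSD < 5 Å,

with the boundary semantics "reject if TM < 0.7 or RMSD ≥ 5 Å", plus
generous length caps (≤ 2000 residues, ≤ 400 ligand atoms) exposed in
config. TM-score uses the shared-sequence residue correspondence (no
alignment search), `d0 = max(1.24·(M−15)^{1/3} − 1.8, 0.5) Å`, is
normalized by the target length, and optimizes the superposition by
TM-weighted iterative re-fitting from several contiguous-fragment starts
(whole chain, both halves, middle half; at most 20 iterations each).
Complexes whose resolved sequence differs from the declared full sequence
(unresolved residues, i.e. sequence gaps) are dropped before the filter.

## Network

The published approach fine-tunes a large pretrained structure-prediction
backbone; this package instead uses a compact rotation-equivariant
message-passing network with the same contract (state + time + sequence +
bond graph → coordinates, confidence, affinity), so that every surrounding
component — priors, coupling, path, solver, ranking — is exercised
faithfully at desk scale. Messages flow on a radius graph (6 Å cutoff)
over all heavy atoms with ligand bond edges always present. Scalar
features: residue one-hot and a Cα flag for protein atoms, element and
bond-degree one-hots for ligand atoms, and `t` as a global scalar. Edge
features: a radial basis of the input distance, type flags
(protein–protein / protein–ligand / ligand–ligand / bond) and the current
distance. Coordinate updates are gated sums of relative-position vectors
(EGNN-style), so coordinates transform equivariantly under rigid motions
while all scalar heads are invariant; the coordinate gates are
zero-initialized, making the untrained network the identity map — an
untrained model is a no-op flow, which stabilizes early sampling. Default
width 48, depth 3.

The network and its training loop run on a small reverse-mode automatic
differentiation core over NumPy float64 arrays (`apoflow.nn.autodiff`),
with exactly the operation set the model needs; gradients are verified
against finite differences in the test suite. Optimization uses Adam
(lr 2e-3, cosine-decayed to 1e-4 by default in the benchmark).

## Confidence labels

Per-residue lDDT: for all atom pairs in different residues with reference
distance < 15 Å, the fraction of thresholds {0.5, 1, 2, 4} Å within which
the predicted distance preserves the reference distance, averaged per
residue; each ligand fragment counts as one pseudo-residue so pocket
residues' labels feel ligand placement errors. The confidence head
predicts these labels with a sigmoid output in [0, 1].

## Sampling

Integration runs `i = 40` uniform timesteps (default) from `t = 0` to 1.
The default solver is the Variance-Diminishing ODE: with `t = n/i`,
`s = (n+1)/i`, `r = (1−s)/(1−t)`,

    x_{n+1} = clamp(r·η)·x_n + clamp((1−r)·η)·v(x_n, t),

with `η = 1` and each scalar coefficient clamped to `[1e-6, 1−1e-6]`. The
ratio form `(1−s)/(1−t)` is the reading under which the two coefficients
sum to η, every update with η = 1 is a convex combination, and the weight
on the model estimate grows sharply at late timesteps — damping the
variance of early, unreliable predictions (verified empirically against
the Euler comparator). The clamp applies to the scalar coefficients, the
only dimensionally coherent choice. The network is evaluated at `t = n/i`
within each step; the final state is the holo estimate, on which the
confidence and affinity heads are evaluated once more at `t = 1`. A plain
Euler solver on the implied velocity field `(v − x)/(1 − t)` is provided
as a comparator; with a constant oracle it telescopes onto the exact
straight-line path. Sampling is a deterministic ODE; stochasticity enters
only through the prior draw. Generated samples are ranked by mean
per-residue confidence.

A structural note: at `η = 1` the VD-ODE coefficient `r = (1−s)/(1−t)`
equals `1 − (1/i)/(1−t)`, so the update coincides with the Euler solver
on the implied velocity field except where the clamp binds — chiefly the
final step, whose pred-coefficient `1` is clamped to `1−1e−6`. Against
this comparator the measured final-state variance reduction under a
noisy oracle is therefore strictly positive but small (the clamp mixes a
sliver of the lower-variance running state into the final estimate);
larger reductions appear at `η < 1` or against solvers that consume
early model estimates at full weight.

## Synthetic fixtures

The toy generator emulates the apo-to-holo training regime with no
external data: a 24-residue ideal-geometry helix (Cα plus one pseudo
side-chain atom per residue, random sequence), a pocket defined as the six
residues nearest the Cα centroid, and a ligand from a fixed ten-fragment
library (methane, water, ethane, methanol, ethanol, ethylamine,
cyclopropane, cyclobutane, benzene, cyclohexane) whose embedded conformer
is placed with its centroid at the pocket center in a seed-determined
orientation. The apo state hinges the C-terminal half about the midpoint
residue by 4° around a seed-determined axis and adds 0.1 Å jitter —
chosen so that every generated pair passes the coupling filter with
margin (TM ≈ 0.9, RMSD ≈ 0.3 Å over 200 seeds) while still exhibiting a
genuine pocket-moving conformational change. Affinity labels follow a
known geometric rule, `pK = 2 + 0.25 · #{protein–ligand atom pairs < 4 Å}`
clipped to [2, 12], so the affinity head has a learnable signal and the
rule is exactly recoverable by regression on the contact count.

What the fixtures do **not** emulate: real side-chain chemistry and
packing, solvent, multi-domain folds, large loop motions, crystal
artifacts, label noise in measured affinities, and ligands beyond small
rigid fragments. Passing the toy benchmark therefore demonstrates that the
generative machinery (priors → coupling → CFM → VD-ODE → ranking) is
implemented correctly and can be trained, not that the compact network
reaches published accuracy on real complexes.

An intrinsic ceiling of the toy task: the reference ligand orientation is
seed-random and not inferable from the protein, so on held-out complexes
even a perfect model can at best place a perfect conformer at the correct
center in some canonical orientation; the residual symmetry-corrected RMSD
is then the mismatch between that orientation and the random reference
one, which the fragment library's symmetric members keep small.

## Benchmark problem sizes

The standard toy benchmark trains on 80 complexes (of 100; deterministic
hash-based 80/20 split) for 4500 Adam steps at batch size 4, then docks
the 20 held-out complexes with 5 samples each at 40 VD-ODE steps and
scores symmetry-corrected ligand RMSD (receptor frame, no superposition,
minimized over bond-graph automorphisms) of the top-ranked sample,
fraction of all samples under 2 Å, and Pearson correlation of predicted
vs labelled affinity. These sizes keep a full train-and-evaluate cycle in
a few CPU-minutes while leaving the affinity range (≥ 3 pK across the
set) and ligand diversity intact. The affinity correlation is reported as
a median over three seeds; because it is insensitive to late training
(≈ 0.99 from 2000 steps on), the two replicate seeds train at 2500 steps
while the canonical run uses the full schedule.

## Numerical choices and degenerate inputs

- Eigenvalues below 1e-9 count as the Laplacian null space.
- Weighted Kabsch raises on under-determined problems (fewer than three
  positively weighted points, collinear/coincident weighted clouds)
  rather than returning an arbitrary rotation.
- The VD-ODE coefficient clamp keeps both coefficients in
  `[1e-6, 1−1e-6]`, so the final step lands on the model estimate up to a
  1e-6 admixture of the previous state.
- Vector norms inside the network are smoothed (`sqrt(Σx² + 1e-12)`) so
  gradients stay finite for coincident atoms.
- PDB I/O: altlocs resolved by highest occupancy; non-standard residues
  and residues lacking a Cα are dropped with a logged warning; hydrogens
  are stripped everywhere; multi-chain structures concatenate into one
  sequence with chain identifiers retained.
- Training aborts with a diagnostic when the loss becomes non-finite.

## Known limitations

- The compact network cannot represent the sequence- and
  chemistry-dependent structure priors of a large pretrained backbone;
  its accuracy statements are toy-scale only.
- The harmonic prior is unweighted; bond orders and element-dependent
  bond lengths are ignored at `t = 0` (the flow must correct them).
- Symmetry-corrected RMSD enumerates bond-graph automorphisms by brute
  force and is intended for ligands up to ~40 heavy atoms.
- Covalent ligands, nucleic-acid chains, protonation states and mmCIF
  input are out of scope.
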