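# Methods

## The problem

Fixed-backbone protein design discretizes every side chain into candidate
conformations-and-identities ("rotamers") and searches for the selection of
one rotamer per position that minimizes a score expressible as one-body and
two-body energy tables. The solution space is `D^N` for `N` positions and
`D` rotamers per position, so both classical annealers and quantum
formulations (one qubit per rotamer in the one-hot QPacker mapping) benefit
enormously from pruning rotamers that the optimization would never keep.
This package implements (i) a graph convolution designed for the data this
problem produces, (ii) a classifier that predicts which rotamer bins a
packing run will visit at a given position, and (iii) the pruning and
resource-accounting machinery that converts those predictions into smaller
problems.

## The XENet layer

Residue-interaction graphs are *symmetric directed graphs*: edge (i, j)
exists iff (j, i) exists, but the two directions carry different attribute
vectors because most geometric pair features (local-frame displacement,
signed sequence offset) are direction dependent. XENet treats each ordered
pair on an edge as a unit. For every such pair it computes a feature stack

    s_ij = phi_s(x_i || x_j || e_ij || e_ji)

(a depth-2 PReLU MLP with S_h channels per layer), aggregates the stacks
separately along the outgoing and incoming directions using scalar sigmoid
self-attention gates,

    s_i_out = sum_{j in N(i)} a_out(s_ij) * s_ij
    s_i_in  = sum_{j in N(i)} a_in(s_ij)  * s_ji,

and updates both nodes and edges:

    x'_i  = phi_n(x_i || s_i_out || s_i_in)
    e'_ij = phi_e(s_ij).

Nodes with empty neighborhoods use zero vectors for both aggregates. Two
reference layers are provided for comparison: CrystalConv (gated residual
aggregation over `x_i || x_j || e_ji`, sigmoid gate, softplus core) and the
edge-conditioned convolution ECC (a filter-generating network maps each
incoming edge attribute to a full weight matrix; mean aggregation plus
bias).

Decisions where the layer definitions leave freedom:

* **The a_in gate argument is `s_ij`.** The incoming aggregate gates the
  reversed stack `s_ji` by a score computed from `s_ij`. This is the layer
  definition taken literally; a `gate_arg_swapped` flag implements the
  plausible alternative `a_in(s_ji)` for ablation and is off by default.
* **phi_n and phi_e have depth 1** (phi_s is fixed at depth 2); depths are
  configurable. This is the simplest consistent reading of the update
  equations. Published parameter totals for XENet-based models cannot be
  reconstructed from the stated architecture under any documented reading,
  so they are treated as approximate guidance; the CrystalConv per-layer
  count (12,838 at F=49, S=32) *is* reproduced exactly and pins down the
  CrystalConv formulation (sigmoid gate, softplus core, residual update,
  message key `x_i || x_j || e_ji`).
* **PReLU slopes are per-channel**, initialized at 0.25; weights are
  fan-in-scaled uniform (limit `sqrt(6/fan_in)`); biases start at zero.
* **ECC internals**: mean aggregation, no root-weight term, one hidden FGN
  layer of width S_h with ReLU. One concrete, documented variant.

All forwards are implemented once, on a small in-package reverse-mode
automatic-differentiation core over numpy arrays (`fixbbgcn._autodiff`),
and verified against independent per-node/per-edge double-loop
transcriptions of the defining equations (tolerance 1e-6) plus permutation
equivariance (1e-5) in the test suite.

## The FixbbGCN classifier

Input graphs have up to 30 nodes, F = 46 node attributes and S = 28 edge
attributes. Node and edge attributes first pass through per-node/per-edge
dense ReLU layers (widths F_h, S_h), then `n` message-passing layers of the
chosen kind; the final XENet layer omits its edge output (those parameters
are never used and are not created or tallied). The conv output is
concatenated with the *raw* input node attributes — a skip connection that
counteracts over-smoothing — cropped to the focus node, and passed through
a 100-unit ReLU layer and a 54-unit sigmoid output. Graphs smaller than the
maximum are zero-padded at model-input time with a node mask excluded from
every aggregation (stored archives are never padded); predictions are
therefore exactly independent of padding width, and invariant to any
permutation of non-focus nodes.

Training: Adam (lr 0.001), mean binary crossentropy over all 54 outputs,
computed in the numerically stable logits form during optimization and with
probability clipping at 1e-7 for reported metrics. The learning rate is
divided by 10 when validation loss fails to improve by more than 0.001 for
2 consecutive epochs; training stops after a 5-epoch plateau; the weights
of the best-validation epoch are restored. The LR monitor and the stopping
monitor run independently. Batches are padded only to the largest graph in
the batch. All shuffling and initialization is seeded; runs are
reproducible bit-for-bit in a single-threaded numpy.

ROC AUC is micro-averaged: all (label, score) pairs across samples and the
54 outputs are pooled and a single AUC computed (midpoint tie handling).
Macro-averaging over outputs was the alternative; micro was chosen because
many of the 54 bins are rare and macro-averaging over near-empty columns is
unstable at desk scale.

## The synthetic data pipeline

The generator emulates the shape of a structure-derived pipeline without
any molecular modelling software:

* **Backbones** are self-avoiding random walks: 3.8-unit steps (the
  physical consecutive-residue spacing), rejection below 4.0 units for
  non-adjacent pairs.
* **Graphs** connect residues within 12 distance units, capped at the 29
  nearest neighbors per node (edges must fit both endpoints' caps,
  preserving symmetry). The 46/28 attribute layout is an invented stand-in
  that matches the real dimensions and, crucially, the real *symmetry
  structure*: some edge-attribute slots are symmetric across the two
  directions of an edge (distance, |sequence offset|, shared pair latents)
  and some antisymmetric (signed offset, frame-dependent latents). It does
  not reproduce any published feature list.
* **Rotamer bins**: 54 bins — ALA, GLY and PRO take one bin each (PRO is
  deliberately never subdivided: eliminating proline rotamers is high-risk,
  low-reward), the remaining 17 amino acids three bins each for the chi1
  wells. Well boundaries are [0, 120) = g+, [120, 240) = t, [240, 360) = g-
  after mod-360 normalization; the wells are named in the field but
  boundary values are a documented convention of this package. Bin layout:
  ALA = 0, GLY = 1, PRO = 2, then the 17 codes alphabetically x (g+, t, g-).
* **Packing problems** plant one-body energies coupling node attributes to
  per-rotamer embedding vectors, and two-body energies coupling embedding
  pairs to the symmetric *and antisymmetric* combinations of the two
  directional edge-attribute vectors. The antisymmetric term makes the
  ground truth genuinely direction dependent — a layer that ignores edge
  direction cannot represent it. The planted maps are drawn once per
  problem (standard normals scaled by 1/sqrt(dim)); every table entry gets
  N(0, 0.1) noise. Tables are scaled by `energy_scale` = 3.0 so that
  typical rotamer energy gaps sit at or above the recording-cutoff
  temperature, as real side-chain energetics do relative to k_B·T — without
  this the low-temperature occupancy visits every bin and labels carry no
  energetic information.
* **Labels** come from simulated annealing: the toy annealer runs Metropolis
  single-rotamer substitutions under a geometric temperature schedule
  (generation default 6.0 -> 0.15 over 400 sweeps, in k_B·T energy units),
  records the representative rotamer per position per sweep, discards steps
  hotter than 3.0 (the analog of masking trajectory above 1,500 K, where
  k_B·T exceeds 3.0 kcal/mol), and sets bit b when bin b held the
  representative state for more than 0.1% of the retained steps. The
  generation schedule starts *above* the cutoff so the thermal mask has a
  real effect at toy scale. Every emitted label has at least one set bit
  (the final representative bin always clears the threshold); a backbone
  violating this is regenerated from a fresh derived seed.

What passing tests on this data do and do not show: they demonstrate that
the architecture can extract single-position, multi-label structure from
graphs with direction-dependent edge attributes and annealing-derived
labels at the stated dimensions — not that it reaches any particular
accuracy on real structures, whose features, energetics and label
statistics differ.

## Pruning and resource accounting

A rotamer survives when the classifier's score for its bin clears the
cutoff; survival is inclusive (`score >= cutoff`), and the -1.0 control
keeps everything because sigmoid outputs are non-negative. A position whose
mask would remove all its rotamers keeps its single best one-body rotamer
(a position must stay packable; the guard is this package's choice).
Pruning slices the energy tables without recomputation, so energies of
surviving assignments are preserved exactly. The report tracks: logical
qubits = total rotamer count (one-hot annealer mapping), with the
information-theoretic `sum(log2 D_i)` as a secondary column; stored
pair-energy entries as the memory proxy (hardware RAM is not modelled); and
the solution-space factor `prod(D'_i / D_i)`, computed in log10 space so it
survives underflow (uniform 60% retention gives 0.006 at N = 10 and one
part in 2.9e183 at N = 827).

The cutoff sweep runs the control first, re-packs each pruned problem with
`repeats` independently seeded annealing runs (seed substreams via
`numpy.random.SeedSequence(seed).spawn`), and reports mean/sd energy
alongside the resource columns, sorted by retention descending.

The exhaustive enumerator (guarded at 10^6 states, lexicographic
tie-break) is the annealer's correctness oracle on tiny instances.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen once: backbones of
10-20 residues, 8 rotamers per position, 400-sweep schedules, datasets of
~2,600 samples (170 backbones) split 2,000 / 500, and a 3-layer XENet with
F_h = 32, S_h = 16 for the end-to-end learnability check. Annealer
correctness is checked on 4-position / 3-rotamer instances against the
81-state enumeration with a long, slowly cooled schedule (3.0 -> 0.02 over
3,000 sweeps): single-rotamer Metropolis moves cannot escape one-move local
minima once cold, so matching the global optimum is a long-schedule
property — about 94% of random instances converge under this schedule, the
remainder being deep multi-move traps. The default packing schedule
(3.0 -> 0.3, 200 sweeps) trades some of that convergence for speed.
Probability clipping at 1e-7; oracle tolerance 1e-6;
equivariance tolerance 1e-5 (sums over permuted neighbors reorder floating
point additions).

## Known limitations

* Real-structure featurization is out of scope; the synthetic attribute
  layout shares dimensions and symmetry structure with real features, not
  their content.
* Published absolute losses/AUCs of the original use case require the
  original structure-derived dataset and are not reproduced here.
* The toy annealer's schedule is a stand-in; real packers use adaptive
  schedules and rotamer-substitution heuristics this package does not
  model.
* ECC and CrystalConv follow one documented variant each; other published
  variants (root weights, alternative gates) would change parameter counts.
* Training determinism is guaranteed for single-threaded BLAS; multi-
  threaded reductions may reorder sums.
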