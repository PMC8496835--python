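# fixbbgcn

Edge-aware graph convolutions for pruning rotamers in fixed-backbone
protein design.

Fixed-backbone design discretizes side chains into *rotamers* and searches
the `D^N` space of one-rotamer-per-position selections for the minimum of a
sum of one-body and two-body energies. Classical simulated-annealing
packers, exact solvers, and quantum-annealer formulations (one qubit per
rotamer) all pay for every rotamer carried into that search: qubits scale
linearly with rotamer count, pair-energy memory quadratically, and the
solution space as `retention^N`. This package provides the machinery to
*learn* which rotamer bins a packing run will actually visit at each
position — and to prune the rest.

The core is **XENet**, a message-passing layer built for the structure of
residue-interaction graphs: a *symmetric* edge set (edge (i, j) exists iff
(j, i) does) carrying *asymmetric* attribute vectors, because geometric
pair features depend on direction. For each ordered pair on an edge XENet
computes a feature stack

```
s_ij    = phi_s(x_i || x_j || e_ij || e_ji)
s_i_out = sum_j a_out(s_ij) * s_ij
s_i_in  = sum_j a_in(s_ij)  * s_ji
x'_i    = phi_n(x_i || s_i_out || s_i_in)
e'_ij   = phi_e(s_ij)
```

so a node's update sees both the messages it sends and the messages it
receives, and edge attributes are themselves updated rather than treated as
static input. CrystalConv and edge-conditioned convolution (ECC) layers are
included as baselines, all three verified against independent double-loop
transcriptions of their equations and tested for permutation equivariance.

On top of the layer sits **FixbbGCN**, a single-node multi-label classifier
(54 rotamer bins: one each for ALA/GLY/PRO, three chi1 wells for the other
17 amino acids), plus a synthetic pipeline that emulates the training-data
generation end to end — backbones, residue graphs with 46/28 node/edge
attributes, planted direction-dependent energies, and occupancy labels from
a Metropolis annealer under the more-than-0.1%-of-the-recorded-run rule —
and the pruning/resource-accounting tools (cutoff masks, sliced energy
tables, qubit counts, pair-entry memory, solution-space factors).

Everything runs on numpy; the network is trained with an in-package
reverse-mode autodiff and Adam. No GPU, no deep-learning framework.

## Worked example

```python
import numpy as np
from fixbbgcn import (
    FixbbGCN, FixbbGCNConfig, TrainConfig, generate_dataset,
    make_packing_problem, build_protein_graph, sample_backbone,
    extract_focus_subgraph, apply_cutoff, prune_problem,
    solution_space_factor,
)

# 1. synthetic labeled data: 20 backbones -> ~300 single-position samples
ds = generate_dataset(20, seed=0)
train_ds, val_ds = ds[:250], ds[250:]

# 2. a 3-layer XENet classifier
model = FixbbGCN(FixbbGCNConfig(conv_kind="xenet", n_conv_layers=3,
                                F_h=32, S_h=16), seed=0)
res = model.fit(train_ds, val_ds, TrainConfig(max_epochs=5, seed=0))
print(res.summary())

# 3. score every position of a fresh problem, prune at the -1.0 control
#    and at cutoff 0.3
coords = sample_backbone(12, seed=1)
g = build_protein_graph(coords, seed=1)
problem = make_packing_problem(g, rotamers_per_position=6, seed=1)
scores = np.stack([model.predict(extract_focus_subgraph(g, i, 30, coords))
                   for i in range(12)])
_, control = prune_problem(problem, [apply_cutoff(s, -1.0) for s in scores])
print(control.retention, control.logical_qubits_after)
_, pruned = prune_problem(problem, [apply_cutoff(s, 0.3) for s in scores])
print("cutoff 0.3 ->", pruned.retention, pruned.logical_qubits_after)

factor, log10f = solution_space_factor(0.6, 10)
print(f"60% retention at N=10 rescales the space by {factor:.3g}")
```

Output of the summary and accounting lines from this run:

```
FixbbGCN fit results
====================
conv kind        : xenet
conv layers      : 3
F_h / S_h        : 32 / 16
trainable params : 27904
epochs run       : 5
best epoch       : 4
best val BCE     : 0.4310
final val AUC    : 0.5224
best val AUC     : 0.5419
1.0 72
cutoff 0.3 -> 0.5972222222222222 43
60% retention at N=10 rescales the space by 0.00605
```

Five epochs on 250 samples only begins to learn (AUC 0.54 and climbing);
the acceptance run below trains on 2,000 samples until validation micro-AUC
clears 0.85. The control cutoff (-1.0) keeps all 72 rotamers — retention
1.0 — because sigmoid scores are non-negative, while cutoff 0.3 keeps 43
(retention 0.60, so 40% fewer logical qubits); `0.00605 ~ 1/165` is the
closed-form solution-space rescaling for uniform 60% retention at 10
positions.

A command-line interface wraps the same workflows:

```
fixbbgcn generate --n-graphs 170 --seed 0 --out data/
fixbbgcn train --train data/dataset.jsonl --val data/dataset.jsonl \
    --conv xenet --layers 3 --fh 32 --sh 16 --seed 0 --out run/
fixbbgcn evaluate --model run/checkpoint.json --data data/dataset.jsonl
fixbbgcn sweep --n-positions 20 --cutoffs -1,0.1,0.3 --out sweep/
fixbbgcn report --sweep sweep/sweep.csv
```

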