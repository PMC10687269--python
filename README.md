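# metabind

Protein-specific meta-learning for drug–target interaction (DTI) prediction,
with weakly supervised binding-pocket detection.

Most DTI classifiers generalize poorly to proteins and molecules absent from
their training data, because pair-input models can exploit annotation-degree
shortcuts instead of binding physics. `metabind` treats *each protein as a
learning task*: a graph-based predictor is meta-trained across many protein
tasks (MAML++-style) so that its initialization transfers zero-shot to
unseen proteins and adapts few-shot from a handful of measured interactions.
It is aimed at computational chemists and ML researchers who need
leakage-controlled DTI benchmarks and an interpretable pocket signal at desk
scale.

## The model

A protein is a residue contact graph `G_p` (nodes = residues located at
their Cα atoms, edges where the Cα–Cα distance is below 8 Å, node features =
per-residue embedding vectors supplied as input, e.g. from a protein
language model). A molecule is a heavy-atom graph `G_m` with OGB-style
categorical atom/bond features. The base predictor scores one
(protein, molecule) pair:

1. two GCN stacks (`H^(l+1) = ReLU(Â H^(l) W^(l) + b^(l))`, `Â` the
   symmetrically normalized adjacency with self-loops) encode both graphs;
2. a **subgraph information bottleneck (SIB)** module assigns every residue
   a soft pocket membership `Z ∈ ℝ^{n×2}` (row-stochastic, column 0 =
   pocket) from `[h_i ‖ G_m]`, and pools the pocket embedding
   `G_sub = (Zᵀ H)[0]`;
3. an MLP on `[G_m ‖ G_sub]` emits the binding probability.

Training minimizes

    L_base = L_cls + λ₁·L_conn + λ₂·L_MI ,   λ₁ = λ₂ = 0.05

where `L_cls` is binary cross-entropy, `L_conn` drives `Z` toward hard,
internally connected parts (`MSE(diag(Norm(Zᵀ A Z)) − diag(I₂))`), and
`L_MI` is a Donsker–Varadhan mutual-information proxy between whole-protein
and pocket embeddings whose critic is maximized by inner gradient-ascent
steps. Minimizing `L_MI` over the encoders compresses the pocket subgraph —
the information-bottleneck view of "molecules bind a pocket, not the whole
protein". The learned `Z`, thresholded at 0.5, is the predicted pocket and
is evaluated against annotated pockets by Jaccard and neighbor-Jaccard
overlap.

Meta-training follows MAML++ with per-layer per-step learnable inner
learning rates (LSLR) and a multi-step query loss (MSL) that weights the
query loss after every inner step — including step 0, the unadapted
parameters used for zero-shot prediction. Task contributions are weighted by
a task-adaptive self-attention module over task embeddings
`[G_sub ‖ mean G_m]`. Everything runs on a small in-package reverse-mode
autodiff engine over numpy (first-order meta-gradients).

Data tooling mirrors standard DTI benchmark practice: affinity binarization
(< 1000 nM binding, > 10⁶ nM nonbinding), network-based negative sampling
(pairs at bipartite shortest-path distance ≥ 7 declared nonbinding),
cd-hit-style sequence clustering at 40% identity, Bemis–Murcko scaffold
grouping, and the transductive / semi-inductive / inductive / few-shot split
taxonomy.

## Worked example

```python
import numpy as np
from metabind.experiments import (make_meta_benchmark, train_synthetic_model,
                                  zero_shot_scores, pocket_recovery)

mb = make_meta_benchmark(seed=1)          # 68 proteins, 120 molecules
state = train_synthetic_model(mb, seed=1) # ~2-4 min on one CPU
labels, scores, per_protein = zero_shot_scores(state, mb.test_tasks)
print(f"zero-shot mean per-protein AUROC: "
      f"{np.mean(list(per_protein.values())):.3f}")
rec = pocket_recovery(state, mb, mb.test_tasks, seed=1)
print(f"pocket Jaccard {rec['jaccard']:.3f} "
      f"vs random baseline {rec['random_jaccard']:.3f}")
```

Output (seed 1):

```
zero-shot mean per-protein AUROC: 0.949
pocket Jaccard 0.426 vs random baseline 0.057
```

The benchmark here is synthetic (planted pockets, a planted
pocket-type/molecule-type binding rule, 5% label noise), so the numbers mean:
the meta-learner transfers the binding rule to proteins from families and
molecules from scaffold groups it has never seen (AUROC well above the 0.5
chance level), and the weakly supervised SIB module localizes the planted
pocket far better than size-matched random residue sets.

A thin CLI wraps the library for shell use:

```bash
metabind meta-train --interactions interactions.tsv --graphs graphs/ \
    --out model.json --seed 0 --embed-dim 32
metabind predict --ckpt model.json --protein P001 --molecules mols.tsv \
    --graphs graphs/ [--finetune few.tsv --steps 30]
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic benchmark from the seed, meta-trains the model
from scratch, evaluates zero-shot transfer, few-shot fine-tuning and pocket
recovery on the held-out protein families and scaffold groups, prints a
summary to stderr and writes the results JSON to `--out`.
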