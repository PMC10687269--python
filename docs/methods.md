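# Methods

This note documents the models and procedures implemented in `metabind`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Graphs

**Proteins.** A residue contact graph: one node per residue, located at its
Cα atom (the conventional residue point for contact maps); an undirected
edge wherever the Cα–Cα Euclidean distance is strictly below 8 Å. Stored
edge attributes are the distances themselves; the default GCN consumes only
the connectivity (a raw-adjacency mode exists behind a flag, and distances
are retained for downstream use such as neighbor-expanded pocket scoring).
Node features are per-residue embedding vectors supplied by the caller as a
plain matrix — in production these come from a protein language model
(width 1280); the library never executes such a model, and synthetic tests
use width 32.

**Molecules.** Heavy-atom graphs parsed from SMILES with RDKit and encoded
with the OGB-style categorical vocabularies: per atom a 9-tuple (atomic
number, chirality, formal charge, attached-H count, radical electrons,
hybridization, aromatic flag, total degree, in-ring flag), per bond a
3-tuple (bond type, stereo, conjugated flag). Unknown categories map to a
reserved `misc` code. Hydrogens are implicit.

**Labels.** Affinities (Ki/Kd/IC50/EC50, nM) binarize at the standard
thresholds: below 1000 nM binding, above 10⁶ nM nonbinding; the ambiguous
middle is dropped. The partition is monotone by construction.

## Network-based negative sampling

Measured interactions of either label define a bipartite protein–molecule
graph. Unlinked pairs whose shortest-path distance in this graph is at
least 7 hops are emitted as nonbinding records (provenance
`network_negative`). The graph is unweighted, so breadth-first search
computes exactly what Dijkstra's algorithm would, at lower cost. Pairs in
different components (infinite distance) are excluded by default — absence
of network evidence is not evidence of distance — with an
`include_disconnected` switch. The default per-protein cap (`"auto"`) adds
just enough negatives to bring each protein's positive ratio to ≤ 0.5,
matching the augmentation's purpose of relieving annotation imbalance.

## Benchmark splits

Proteins cluster by sequence identity; the built-in stand-in for cd-hit is
greedy longest-first clustering where identity = global-alignment matched
positions / longer sequence length (match 1, mismatch 0, zero gap
penalties — an LCS-style match count via Biopython's PairwiseAligner).
Externally computed cluster maps are accepted verbatim and are the
recommended path at scale. Molecules group by canonical Bemis–Murcko
scaffold (acyclic molecules share the empty scaffold).

Scaffolds split 95/5 into train/test sets with zero overlap. Clusters
containing any protein with fewer than 20 associated molecules become test
clusters. Train = 95% of train-cluster proteins × train scaffolds;
transductive = the held-out 5% × train scaffolds (holdout is drawn only
from clusters that keep at least one train member, so no transductive
cluster is unseen); inductive = test-cluster proteins × test scaffolds;
semi-inductive = the remaining records (the operational "rest" rule; a
stricter definitional filter is available). Few-shot sets draw exactly 5
binding + 5 nonbinding records per protein of the combined held-out pools;
proteins lacking either count are excluded. All sampling routes through one
seeded generator after a canonical record sort, so the partition is
invariant to input order.

## Base model

Both encoders are GCN stacks, `H^(l+1) = ReLU(Â H^(l) W^(l) + b^(l))` with
`Â = D^{-1/2}(A+I)D^{-1/2}` (the normalization is unstated upstream;
symmetric-with-self-loops is the standard choice, raw adjacency available).
Production widths: protein 1280→512→256→256→256 (4 layers), molecule
256→256→256 (3 layers) after summing nine per-category embedding tables;
desk-scale tests shrink all widths to the synthetic feature width. Pooling
for graph-level embeddings is the mean (sum behind a flag).

The SIB module computes the assignment matrix `Z = softmax(MLP([h_i ‖
G_m]))` per residue — pocket membership is molecule-conditional, since a
pocket is defined by what binds it — and pools `G_sub = (Zᵀ H)[0]`. Its
training signal combines:

* the classification loss (pocket must predict binding);
* a connectivity loss `mean((diag(Norm(Zᵀ A Z)) − 1)²)` driving `Z` toward
  hard, internally connected parts (a 1e-12 guard handles parts with no
  incident edge mass);
* a Donsker–Varadhan mutual-information proxy between whole-protein and
  pocket embeddings, `mean_i f(G_i, G_sub_i) − log mean_{i≠j} exp f(G_i,
  G_sub_j)`, with a dense critic (two hidden ReLU layers) maximized by
  plain gradient ascent at rate 0.01 for 20 steps. The critic lives outside
  the outer optimization (the argmax constraint). Whether the ascent runs
  inside every forward or less often is unspecified upstream; at desk scale
  it runs on the first support evaluation of each task per outer step
  (configurable), which leaves the loss values unchanged to within critic
  staleness and roughly halves training cost.

Total: `L_base = L_cls + 0.05·L_conn + 0.05·L_MI`. The classifier is an
MLP with two hidden layers on `[G_m ‖ G_sub]`, terminal sigmoid clamped to
[1e-7, 1−1e-7].

Ablation switches reproduce the standard comparisons: `sib_enabled=False`
replaces `G_sub` with the pooled whole-protein embedding;
`random_z=True` draws a row-stochastic `Z` from the seeded generator (no
gradient reaches the assignment MLP); `attention_enabled=False` forces
uniform task weights.

## Meta-learning

Each protein is one task: support = 5 binding + 5 nonbinding records,
query = 5 records. Inner adaptation takes 5 gradient steps with per-layer
per-step learnable rates (LSLR, initialized at 0.01, unconstrained in sign
thereafter). Meta-gradients are first order: inner gradients are constants,
so a query loss at an adapted point contributes its local gradient to the
initialization, while the learning rates still receive exact gradients
through the linear update equations.

The multi-step query loss evaluates the query set at the unadapted
parameters (step 0) and after every inner step. Because this model's
primary deployment is zero-shot — the meta-initialization is used directly
on unseen proteins — the step-importance vector υ keeps half its mass on
step 0, with the remainder uniform across the adapted steps. (The common
alternative, annealing all mass toward the final step, optimizes purely
post-adaptation performance; it measurably degrades zero-shot transfer on
the synthetic benchmark and is available via configuration.)

Gradient-based meta-learning is unstable from a random initialization: in
a large fraction of runs the optimizer settles into an adaptation-reliant
basin where the inner loop fits each task while the shared initialization
never learns the transferable rule (training-side zero-shot AUROC stays at
chance while the meta loss falls). Two stabilizers address this, both
inside the outer-step budget:

* **Warmup.** The first `warmup_frac` (default 0.8) of the outer steps run
  with inner-loop length zero and all MSL mass on the unadapted step —
  plain episodic supervised training of the shared predictor. The
  remaining steps run the full inner loop, LSLR, MSL and task attention.
* **Restart probes.** Several short probe runs (default 2 × 60 steps) start
  from different initializations; the probe with the best *training-side*
  zero-shot AUROC continues on the tail of the global schedule. Probes
  count against the outer-step budget, and model selection never touches
  held-out data.

Task weights η come from scaled dot-product self-attention over the task
embeddings `[mean G_sub ‖ mean query G_m]`, followed by a learnable scalar
projection (zero-initialized, so η starts exactly uniform) and a softmax
over the batch. η is nonnegative, sums to one, and is
permutation-equivariant in the batch. Because η is trained jointly with
the loss it weights, it carries a degenerate shortcut — down-weighting
hard tasks lowers the objective without learning anything — which at small
task batches (B = 4) measurably hurts if allowed to act during warmup;
attention therefore applies only in the meta phase.

The outer update is AdamW-style: Adam moments on all trainable groups
(base parameters, LSLR rates, attention), decoupled weight decay on the
base parameters only, cosine-annealed meta learning rate. Weight decay is
load-bearing: without it the shared initialization memorizes the training
proteins instead of learning the transferable binding rule.

Few-shot fine-tuning clones the meta parameters and descends the full base
loss on the 5+5 records (default 100 steps at rate 0.005); the meta state
is untouched.

## Pocket evaluation

A predicted pocket is the residue set with `Z[i,0] ≥ 0.5` (inclusive).
At desk scale the connectivity and MI pressures (λ = 0.05) have not yet
hardened or oriented `Z` by the end of training: the memberships rank the
planted pocket almost perfectly (per-protein rank AUROC ≈ 0.99) but with a
floating per-protein offset and an arbitrary column orientation, so the
fixed threshold measures calibration rather than localization. The
experiment harness therefore also provides size-matched rank extraction:
the k = ⌈pocket_fraction·n⌉ residues with the most extreme memberships,
taking whichever end of the ranking forms the denser subgraph (the
bottleneck subgraph is by construction the compact, connected part). The
random baseline receives the same size prior. Overlap with an annotated
pocket uses the Jaccard coefficient; the
neighbor-expanded variant scores against the truth union its first-order
contact-graph neighbors, crediting predictions that land adjacent to the
annotation. Note the expanded score is not pointwise ≥ the plain score for
arbitrary predictions (an exact-truth prediction scores 1.0 plain but
|truth|/|expanded| expanded); it is the appropriate measure when
predictions systematically spill over the pocket boundary, which is the
regime trained models exhibit. The random baseline draws size-matched
residue sets uniformly, seeded.

AUROC is the Mann–Whitney statistic with tie mid-ranks and AUPRC the
step-interpolated precision–recall integral (scikit-learn's
implementations); per-protein reports exclude proteins lacking either
class.

## Synthetic benchmark

The generator emulates the *shape* of a real DTI benchmark, not its
chemistry:

* protein chains are 3.8 Å-step self-avoiding random walks whose 8 Å
  contact graphs are sparse and connected; a spatially contiguous 15% of
  residues is the planted pocket;
* each pocket carries one of 4 orthonormal unit signature vectors added to
  its residues' features; background features are N(0, 0.05²), and half of
  the background residues additionally carry a half-strength decoy
  signature of a random type. The decoys make whole-graph pooling mis-read
  the pocket type, so localization — not mere aggregation — is required;
  binding itself still depends only on pocket-local features. The scales
  are calibrated so the stated identifiability properties hold: a linear
  probe separates pocket from background residues (AUROC ≫ 0.95), and the
  planted binding rule is learnable to AUROC ≥ 0.8 by a correctly
  specified learner within a few hundred optimizer updates;
* pocket and molecule types are assigned round-robin, so every type is
  equally represented (uniform marginals with the compositional variance
  of small benchmarks removed);
* molecules are random connected graphs (6–20 atoms) whose atomic-number
  channel is biased by a latent molecule type (marker code with
  probability 0.7); scaffold labels come from a 20-element pool;
* a pair binds iff molecule type matches pocket type, flipped with
  probability 0.05 (so the Bayes-optimal AUROC is slightly below 1, and
  exactly 1 at zero noise).

What a green test establishes: the meta-learner recovers a planted,
pocket-local, type-matching rule and transfers it across protein families
and scaffold groups it never saw; the SIB module localizes the planted
pocket far above the random baseline. What it does not establish: any
statement about real binding free energies, real pocket geometry, chemistry
beyond the categorical encoding, or performance at BindingDB scale.

## Numerical choices

* All neural computation runs on an in-package reverse-mode autodiff engine
  over float64 numpy arrays; gradients are first-order only.
* He-scaled initialization for ReLU-feeding weights, Glorot for linear
  outputs, zero biases; embedding tables N(0, 0.1).
* Probabilities clamp at 1e-7 before the log; connectivity row sums add
  1e-12; softmax and logsumexp are max-shifted.
* Degenerate few-shot/task sampling (too few records of a class) raises a
  skip signal rather than silently unbalancing.
* Ties in clustering order, scaffold sets and record partitions break by
  canonical sort before any seeded draw.

## Known limitations

* Second-order meta-gradients are not implemented (the engine does not
  build differentiable gradient graphs); first-order MAML++ is a documented
  approximation.
* The built-in clusterer is quadratic in the number of sequences; use
  external cluster maps beyond a few thousand proteins.
* The desk-scale model (width 32) is far below the production widths; the
  synthetic benchmark validates mechanism, not capacity.
* Training remains sensitive to the meta learning rate and weight decay,
  consistent with the known instability of gradient-based meta-learning.
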