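"""The protein-specific base predictor.

One forward pass scores a (protein graph, molecule graph) pair:

1. two GCN stacks encode the protein residues and the molecule atoms
   (molecule categorical features first pass through learned per-category
   embedding tables, summed per atom);
2. the subgraph-information-bottleneck (SIB) module assigns every residue a
   soft membership ``Z[i] = (p_pocket, p_rest)`` from the concatenation of its
   embedding with the pooled molecule embedding, and pools the pocket
   subgraph embedding ``G_sub`` as row 0 of ``Z^T G_p``;
3. a classifier MLP on ``[G_m || G_sub]`` emits the binding probability.

The training loss combines binary cross-entropy, a connectivity penalty that
drives ``Z`` toward hard, internally connected parts, and a Donsker-Varadhan
mutual-information proxy between whole-protein and subgraph embeddings whose
critic is maximized by a few plain gradient-ascent steps inside each forward
pass (the critic is never part of the outer descent):

    L_base = L_cls + lambda1 * L_conn + lambda2 * L_MI

All forwards are functional in a flat ``{name: Tensor}`` parameter dict so
the meta-learning loops can evaluate the model at adapted parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import (Tensor, concat, constant, logsumexp, relu, repeat_rows,
                       sigmoid, softmax, tile_rows)
from .graphs import ATOM_FEATURE_DIMS, MoleculeGraph, ProteinGraph

EPS_PROB = 1e-7


@dataclass
class ModelConfig:
    # layer width schedules: first entry is the input width
    protein_widths: tuple = (1280, 512, 256, 256, 256)
    molecule_widths: tuple = (256, 256, 256, 256)
    assign_hidden: tuple = (64,)
    critic_hidden: tuple = (256, 128)
    classifier_hidden: tuple = (256, 64)
    lambda1: float = 0.05          # connectivity weight
    lambda2: float = 0.05          # MI-proxy weight
    assign_init_gain: float = 1.0  # scales phi1 init; breaks Z uniformity
    mi_inner_steps: int = 20       # critic ascent steps per forward
    mi_lr: float = 0.01
    adjacency_norm: str = "sym"    # 'sym' (D^-1/2 (A+I) D^-1/2) or 'raw'
    pooling: str = "mean"          # 'mean' or 'sum'
    sib_enabled: bool = True       # False = whole-protein embedding (SIB-off)
    random_z: bool = False         # random row-stochastic Z (pocket ablation)

    @property
    def embed_dim(self) -> int:
        return self.protein_widths[-1]


def desk_config(embed_dim: int = 32) -> ModelConfig:
    """Small widths for synthetic benchmarks and tests.

    The protein stack is 2 GCN layers here (production uses 4): on the small
    dense synthetic contact graphs, 4 rounds of neighborhood averaging
    oversmooth the residue embeddings into near-identical vectors, which
    erases the per-residue distinctions the pocket-assignment module needs.
    """
    d = embed_dim
    return ModelConfig(protein_widths=(d, d, d),
                       molecule_widths=(d, d, d, d),
                       assign_hidden=(d,),
                       critic_hidden=(d, d),
                       classifier_hidden=(d, d // 2))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _init_w(rng, fan_in, fan_out, relu: bool):
    # He scaling for layers feeding a ReLU, Glorot for linear outputs
    s = np.sqrt(2.0 / fan_in) if relu else np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, s, size=(fan_in, fan_out))


def _mlp_params(rng, prefix, widths, out_dim):
    """Dense stack ``widths[0] -> ... -> widths[-1] -> out_dim``."""
    params = {}
    dims = list(widths) + [out_dim]
    for l in range(len(dims) - 1):
        params[f"{prefix}.{l}.W"] = Tensor(
            _init_w(rng, dims[l], dims[l + 1], relu=l < len(dims) - 2),
            requires_grad=True)
        params[f"{prefix}.{l}.b"] = Tensor(np.zeros(dims[l + 1]),
                                           requires_grad=True)
    return params


def init_params(cfg: ModelConfig, seed: int = 0):
    """Returns ``(params, critic)``: meta-learned parameters and the
    MI-critic parameters (kept outside the outer optimization)."""
    rng = np.random.default_rng(seed)
    d = cfg.embed_dim
    params: dict[str, Tensor] = {}

    pw = cfg.protein_widths
    for l in range(len(pw) - 1):
        params[f"theta_P.{l}.W"] = Tensor(_init_w(rng, pw[l], pw[l + 1], relu=True),
                                          requires_grad=True)
        params[f"theta_P.{l}.b"] = Tensor(np.zeros(pw[l + 1]), requires_grad=True)

    mw = cfg.molecule_widths
    for k, vocab in enumerate(ATOM_FEATURE_DIMS):
        params[f"theta_M.emb.{k}"] = Tensor(rng.normal(0.0, 0.1, (vocab, mw[0])),
                                            requires_grad=True)
    for l in range(len(mw) - 1):
        params[f"theta_M.{l}.W"] = Tensor(_init_w(rng, mw[l], mw[l + 1], relu=True),
                                          requires_grad=True)
        params[f"theta_M.{l}.b"] = Tensor(np.zeros(mw[l + 1]), requires_grad=True)

    params.update(_mlp_params(rng, "phi1", (2 * d,) + cfg.assign_hidden, 2))
    # a near-uniform Z at init starves the assignment MLP of gradient (the
    # pocket pathway only trains once memberships vary across residues), so
    # its weights start larger than He scale...
    for l in range(len(cfg.assign_hidden) + 1):
        params[f"phi1.{l}.W"].data *= cfg.assign_init_gain
    # ...and the output bias starts tilted toward inclusion: residues begin
    # mostly inside the pocket column and training prunes, rather than
    # growing the subgraph from nothing
    params[f"phi1.{len(cfg.assign_hidden)}.b"] = Tensor(np.array([0.5, 0.0]),
                                                        requires_grad=True)
    params.update(_mlp_params(rng, "theta_cls", (2 * d,) + cfg.classifier_hidden, 1))
    critic = _mlp_params(rng, "phi2", (2 * d,) + cfg.critic_hidden, 1)
    return params, critic


def layer_key(name: str) -> str:
    """Group parameter names into layers (for per-layer learning rates)."""
    return name.rsplit(".", 1)[0]


def clone_params(params: dict) -> dict:
    return {k: Tensor(v.data.copy(), requires_grad=True) for k, v in params.items()}


def zero_grads(params: dict) -> None:
    for t in params.values():
        t.grad = None


# ---------------------------------------------------------------------------
# GCN
# ---------------------------------------------------------------------------

def normalized_adjacency(adj: np.ndarray, mode: str = "sym") -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops (or raw A)."""
    if mode == "raw":
        return np.asarray(adj, dtype=float)
    a = np.asarray(adj, dtype=float) + np.eye(adj.shape[0])
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


def gcn_layer(node_embed: Tensor, a_hat: np.ndarray, W: Tensor, b: Tensor) -> Tensor:
    if node_embed.shape[1] != W.shape[0]:
        raise ValueError(f"width mismatch: {node_embed.shape[1]} vs {W.shape[0]}")
    return relu(constant(a_hat) @ node_embed @ W + b)


def encode_protein(graph: ProteinGraph, params: dict, cfg: ModelConfig) -> Tensor:
    """Stacked GCN over the residue contact graph; returns (n, d) embeddings."""
    a_hat = normalized_adjacency(graph.adjacency, cfg.adjacency_norm)
    h = constant(graph.node_features)
    for l in range(len(cfg.protein_widths) - 1):
        h = gcn_layer(h, a_hat, params[f"theta_P.{l}.W"], params[f"theta_P.{l}.b"])
    return h


def _pool(h: Tensor, cfg: ModelConfig) -> Tensor:
    return h.mean(axis=0) if cfg.pooling == "mean" else h.sum(axis=0)


def embed_molecule_features(codes: np.ndarray, params: dict) -> Tensor:
    """Sum the 9 per-category embedding-table rows for each atom."""
    h = params["theta_M.emb.0"][codes[:, 0]]
    for k in range(1, codes.shape[1]):
        h = h + params[f"theta_M.emb.{k}"][codes[:, k]]
    return h


def encode_molecule(graph: MoleculeGraph, params: dict, cfg: ModelConfig):
    """Returns ``(atom_embeddings, pooled_molecule_embedding)``."""
    a_hat = normalized_adjacency(graph.adjacency, cfg.adjacency_norm)
    h = embed_molecule_features(np.asarray(graph.node_features, dtype=int), params)
    for l in range(len(cfg.molecule_widths) - 1):
        h = gcn_layer(h, a_hat, params[f"theta_M.{l}.W"], params[f"theta_M.{l}.b"])
    return h, _pool(h, cfg)


# ---------------------------------------------------------------------------
# SIB module
# ---------------------------------------------------------------------------

def _mlp_forward(x: Tensor, params: dict, prefix: str, n_layers: int) -> Tensor:
    for l in range(n_layers):
        x = x @ params[f"{prefix}.{l}.W"] + params[f"{prefix}.{l}.b"]
        if l < n_layers - 1:
            x = relu(x)
    return x


def sib_assign(protein_nodes: Tensor, molecule_embed: Tensor, params: dict,
               cfg: ModelConfig) -> Tensor:
    """Row-stochastic (n, 2) membership matrix Z; column 0 = pocket."""
    n = protein_nodes.shape[0]
    tiled = constant(np.ones((n, 1))) @ molecule_embed.reshape(1, -1)
    x = concat([protein_nodes, tiled], axis=1)
    logits = _mlp_forward(x, params, "phi1", len(cfg.assign_hidden) + 1)
    return softmax(logits, axis=1)


def random_assignment(n: int, rng) -> Tensor:
    """Row-stochastic Z drawn uniformly (the random-pocket ablation)."""
    z0 = rng.uniform(size=(n, 1))
    return constant(np.concatenate([z0, 1.0 - z0], axis=1))


def subgraph_embedding(Z: Tensor, protein_nodes: Tensor) -> Tensor:
    """Row 0 of ``Z^T G_p``: the pocket-membership-weighted node sum."""
    if Z.shape != (protein_nodes.shape[0], 2):
        raise ValueError(f"Z shape {Z.shape} does not match {protein_nodes.shape}")
    return (Z.T @ protein_nodes)[0]


def connectivity_loss(Z: Tensor, adjacency: np.ndarray) -> Tensor:
    """Mean of ``(p_kk - 1)^2`` with ``p = row-normalize(Z^T A Z)``.

    Zero exactly when each part's row-normalized internal connectivity is 1
    (e.g. Z indicates disconnected components); 0.25 for a uniform Z.
    """
    if adjacency.sum() == 0:
        raise ValueError("graph has no edges")
    c = Z.T @ constant(np.asarray(adjacency, dtype=float)) @ Z
    rowsum = c.sum(axis=1, keepdims=True) + 1e-12   # guard: empty part
    p = c / rowsum
    diag = p[np.arange(2), np.arange(2)]
    return ((diag - 1.0) ** 2).mean()


# ---------------------------------------------------------------------------
# MI proxy (Donsker-Varadhan critic)
# ---------------------------------------------------------------------------

def critic_scores(x: Tensor, critic: dict, cfg: ModelConfig) -> Tensor:
    out = _mlp_forward(x, critic, "phi2", len(cfg.critic_hidden) + 1)
    return out.reshape(-1)


def mi_proxy_loss(whole_embeds: Tensor, sub_embeds: Tensor, critic: dict,
                  cfg: ModelConfig) -> Tensor:
    """DV bound: mean joint score minus log mean off-diagonal exp score."""
    n = whole_embeds.shape[0]
    if n < 2:
        raise ValueError("MI proxy needs a batch of at least 2")
    joint = critic_scores(concat([whole_embeds, sub_embeds], axis=1), critic, cfg)
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    marg = critic_scores(concat([whole_embeds[ii], sub_embeds[jj]], axis=1),
                         critic, cfg)
    return joint.mean() - (logsumexp(marg) - float(np.log(n)))


def fit_critic(whole_data: np.ndarray, sub_data: np.ndarray, critic: dict,
               cfg: ModelConfig, steps: int | None = None) -> None:
    """Gradient-ascend the DV bound over the critic parameters in place.

    Embeddings are treated as constants: this is the inner ``argmax`` over
    the critic, run for ``mi_inner_steps`` at ``mi_lr`` inside each forward.
    """
    steps = cfg.mi_inner_steps if steps is None else steps
    n = whole_data.shape[0]
    if n < 2:
        raise ValueError("MI proxy needs a batch of at least 2")
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    x = np.concatenate([
        np.concatenate([whole_data, sub_data], axis=1),            # joint
        np.concatenate([whole_data[ii], sub_data[jj]], axis=1),    # marginal
    ], axis=0)
    n_layers = len(cfg.critic_hidden) + 1
    ws = [critic[f"phi2.{l}.W"] for l in range(n_layers)]
    bs = [critic[f"phi2.{l}.b"] for l in range(n_layers)]
    # the inputs are constant, so the ascent is a plain dense-MLP loop
    for _ in range(steps):
        acts, h = [x], x
        for l in range(n_layers):
            h = h @ ws[l].data + bs[l].data
            if l < n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        scores = h[:, 0]
        e = np.exp(scores[n:] - scores[n:].max())
        g_out = np.empty_like(scores)
        g_out[:n] = 1.0 / n                 # d(mean joint)/d score
        g_out[n:] = -e / e.sum()            # d(-log mean exp)/d score
        g = g_out[:, None]
        for l in range(n_layers - 1, -1, -1):
            if l < n_layers - 1:
                g = g * (acts[l + 1] > 0)
            gw = acts[l].T @ g
            gb = g.sum(axis=0)
            g = g @ ws[l].data.T
            ws[l].data = ws[l].data + cfg.mi_lr * gw    # ascent
            bs[l].data = bs[l].data + cfg.mi_lr * gb


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def classify(molecule_embed: Tensor, sub_embed: Tensor, params: dict,
             cfg: ModelConfig) -> Tensor:
    x = concat([molecule_embed, sub_embed], axis=0).reshape(1, -1)
    logit = _mlp_forward(x, params, "theta_cls", len(cfg.classifier_hidden) + 1)
    return sigmoid(logit.reshape(())).clip(EPS_PROB, 1.0 - EPS_PROB)


def bce_loss(y: float, y_hat: Tensor) -> Tensor:
    y = float(y)
    return -(y * y_hat.log() + (1.0 - y) * (1.0 - y_hat).log())


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

@dataclass
class ForwardResult:
    prob: Tensor                 # scalar prediction in (0, 1)
    Z: np.ndarray | None         # detached assignment matrix
    Z_graph: Tensor = None       # in-graph assignment (None for SIB-off)
    sub_embed: Tensor = None
    whole_embed: Tensor = None
    molecule_embed: Tensor = None


def pair_forward(protein_nodes: Tensor, molecule: MoleculeGraph, params: dict,
                 cfg: ModelConfig, rng=None) -> ForwardResult:
    """Score one molecule against pre-encoded protein residues (no losses)."""
    _, g_m = encode_molecule(molecule, params, cfg)
    Z = None
    if cfg.sib_enabled:
        if cfg.random_z:
            Z = random_assignment(protein_nodes.shape[0],
                                  rng or np.random.default_rng(0))
        else:
            Z = sib_assign(protein_nodes, g_m, params, cfg)
        g_sub = subgraph_embedding(Z, protein_nodes)
    else:
        g_sub = _pool(protein_nodes, cfg)
    prob = classify(g_m, g_sub, params, cfg)
    return ForwardResult(prob=prob, Z=None if Z is None else Z.data.copy(),
                         Z_graph=Z, sub_embed=g_sub,
                         whole_embed=_pool(protein_nodes, cfg),
                         molecule_embed=g_m)


def batch_forward(protein: ProteinGraph, molecules: list[MoleculeGraph],
                  labels, params: dict, critic: dict, cfg: ModelConfig,
                  rng=None, train: bool = True):
    """Full loss over a batch of molecules for one protein (Box-2 semantics).

    Encodes the protein once, scores every molecule, runs the critic ascent
    on the batch of (whole, sub) embeddings, and returns
    ``(loss, probs, Z_list, results)`` where ``loss`` is
    ``mean BCE + lambda1 * mean L_conn + lambda2 * L_MI``.
    """
    protein_nodes = encode_protein(protein, params, cfg)
    results = [pair_forward(protein_nodes, m, params, cfg, rng=rng)
               for m in molecules]
    probs = [r.prob for r in results]
    n = len(results)

    cls_terms = [bce_loss(y, r.prob) for y, r in zip(labels, results)]
    loss = sum(cls_terms[1:], cls_terms[0]) * (1.0 / n)

    if cfg.sib_enabled and train:
        adj = protein.adjacency
        if cfg.lambda1 != 0.0 and adj.sum() > 0:
            conn = [connectivity_loss(r.Z_graph, adj) for r in results]
            loss = loss + cfg.lambda1 * (sum(conn[1:], conn[0]) * (1.0 / n))
        if cfg.lambda2 != 0.0 and n >= 2:
            whole = concat([r.whole_embed.reshape(1, -1) for r in results], axis=0)
            sub = concat([r.sub_embed.reshape(1, -1) for r in results], axis=0)
            if cfg.mi_inner_steps > 0:
                fit_critic(whole.data, sub.data, critic, cfg)
            loss = loss + cfg.lambda2 * mi_proxy_loss(whole, sub, critic, cfg)
    return loss, probs, [r.Z for r in results], results


# ---------------------------------------------------------------------------
# batched task forward (disjoint-union molecule batch)
# ---------------------------------------------------------------------------

@dataclass
class MoleculeBatch:
    """Precomputed disjoint union of a task's molecule graphs.

    Merging the molecules into one block-diagonal graph lets a whole
    support/query set be scored with a handful of large tensor operations
    instead of per-molecule loops; numerically identical to the looped path.
    """
    codes: np.ndarray        # (sum_n, 9) atom feature codes
    a_hat: np.ndarray        # block-diagonal normalized adjacency
    pool: np.ndarray         # (n_mols, sum_n) mean- or sum-pooling operator
    n_mols: int


def make_molecule_batch(molecules: list[MoleculeGraph],
                        cfg: ModelConfig) -> MoleculeBatch:
    sizes = [m.n_atoms for m in molecules]
    total = sum(sizes)
    codes = np.concatenate([np.asarray(m.node_features, dtype=int)
                            for m in molecules], axis=0)
    a_hat = np.zeros((total, total))
    pool = np.zeros((len(molecules), total))
    off = 0
    for j, (m, n) in enumerate(zip(molecules, sizes)):
        a_hat[off:off + n, off:off + n] = normalized_adjacency(
            m.adjacency, cfg.adjacency_norm)
        pool[j, off:off + n] = (1.0 / n) if cfg.pooling == "mean" else 1.0
        off += n
    return MoleculeBatch(codes=codes, a_hat=a_hat, pool=pool,
                         n_mols=len(molecules))


def _protein_operators(graph: ProteinGraph, cfg: ModelConfig):
    """Adjacency and normalized adjacency, cached on the graph object."""
    key = f"_ops_{cfg.adjacency_norm}"
    cached = getattr(graph, key, None)
    if cached is None:
        adj = graph.adjacency
        cached = (adj, normalized_adjacency(adj, cfg.adjacency_norm))
        object.__setattr__(graph, key, cached)
    return cached


@dataclass
class BatchAux:
    """In-graph tensors from a batched forward, for the task embedding."""
    sub_embeds: Tensor       # (n_mols, d)
    mol_embeds: Tensor       # (n_mols, d)
    whole_embed: Tensor      # (d,)


def batched_task_forward(protein: ProteinGraph, mol_batch: MoleculeBatch,
                         labels, params: dict, critic: dict, cfg: ModelConfig,
                         rng=None, train: bool = True,
                         fit_critic_now: bool = True):
    """Loss and predictions for one protein against a molecule batch.

    Vectorized equivalent of scoring each molecule with
    :func:`base_forward` and averaging the losses; returns
    ``(loss, probs, Z, aux)`` with ``probs`` a (n_mols,) array and ``Z``
    the stacked (n_mols, n_residues, 2) assignments (None for SIB-off).
    """
    adj, a_hat_p = _protein_operators(protein, cfg)
    n = protein.n_residues
    B = mol_batch.n_mols

    # protein encoder
    h = constant(protein.node_features)
    for l in range(len(cfg.protein_widths) - 1):
        h = gcn_layer(h, a_hat_p, params[f"theta_P.{l}.W"], params[f"theta_P.{l}.b"])
    whole = _pool(h, cfg)

    # molecule encoder on the disjoint union
    hm = embed_molecule_features(mol_batch.codes, params)
    for l in range(len(cfg.molecule_widths) - 1):
        hm = gcn_layer(hm, mol_batch.a_hat,
                       params[f"theta_M.{l}.W"], params[f"theta_M.{l}.b"])
    g_m = constant(mol_batch.pool) @ hm                       # (B, d)

    z_stack = None
    if cfg.sib_enabled:
        if cfg.random_z:
            z0 = constant((rng or np.random.default_rng(0)).uniform(size=(B, n)))
        else:
            h_rep = tile_rows(h, B)                           # (B*n, d)
            m_rep = repeat_rows(g_m, n)                       # (B*n, d)
            logits = _mlp_forward(concat([h_rep, m_rep], axis=1), params,
                                  "phi1", len(cfg.assign_hidden) + 1)
            z = softmax(logits, axis=1)                       # (B*n, 2)
            z0 = (z @ constant(np.array([1.0, 0.0]))).reshape(B, n)
        sub = z0 @ h                                          # (B, d)
        z_stack = np.stack([z0.data, 1.0 - z0.data], axis=2)
    else:
        sub = constant(np.ones((B, 1))) @ whole.reshape(1, -1)

    # classifier
    x = concat([g_m, sub], axis=1)
    logit = _mlp_forward(x, params, "theta_cls", len(cfg.classifier_hidden) + 1)
    probs = sigmoid(logit.reshape(-1)).clip(EPS_PROB, 1.0 - EPS_PROB)
    y = np.asarray(labels, dtype=float)
    loss = -(constant(y) * probs.log()
             + constant(1.0 - y) * (1.0 - probs).log()).mean()

    if cfg.sib_enabled and train:
        if cfg.lambda1 != 0.0 and adj.sum() > 0:
            z1 = 1.0 - z0
            az0 = z0 @ constant(adj)
            az1 = z1 @ constant(adj)
            c00 = (z0 * az0).sum(axis=1)
            c01 = (z1 * az0).sum(axis=1)      # equals c10 (A symmetric)
            c11 = (z1 * az1).sum(axis=1)
            p00 = c00 / (c00 + c01 + 1e-12)
            p11 = c11 / (c01 + c11 + 1e-12)
            conn = (((p00 - 1.0) ** 2 + (p11 - 1.0) ** 2) * 0.5).mean()
            loss = loss + cfg.lambda1 * conn
        if cfg.lambda2 != 0.0 and B >= 2:
            w_rep = constant(np.ones((B, 1))) @ whole.reshape(1, -1)
            if fit_critic_now and cfg.mi_inner_steps > 0:
                fit_critic(w_rep.data, sub.data, critic, cfg)
            loss = loss + cfg.lambda2 * mi_proxy_loss(w_rep, sub, critic, cfg)

    aux = BatchAux(sub_embeds=sub if cfg.sib_enabled else
                   constant(np.ones((B, 1))) @ whole.reshape(1, -1),
                   mol_embeds=g_m, whole_embed=whole)
    return loss, probs, z_stack, aux


def base_forward(protein: ProteinGraph, molecule: MoleculeGraph, params: dict,
                 critic: dict, cfg: ModelConfig, label=None, mi_batch=None,
                 rng=None):
    """Single-pair forward: returns ``(prob, L_base, Z)``.

    ``mi_batch`` optionally supplies additional (whole, sub) embedding rows
    (numpy arrays) so the DV term is defined; without it (batch of 1) the MI
    term is skipped.
    """
    protein_nodes = encode_protein(protein, params, cfg)
    r = pair_forward(protein_nodes, molecule, params, cfg, rng=rng)
    if label is None:
        return r.prob, None, r.Z
    loss = bce_loss(label, r.prob)
    if cfg.sib_enabled and cfg.lambda1 != 0.0 and protein.adjacency.sum() > 0:
        loss = loss + cfg.lambda1 * connectivity_loss(r.Z_graph, protein.adjacency)
    if cfg.sib_enabled and cfg.lambda2 != 0.0 and mi_batch is not None:
        extra_w, extra_s = mi_batch
        whole = concat([r.whole_embed.reshape(1, -1), constant(extra_w)], axis=0)
        sub = concat([r.sub_embed.reshape(1, -1), constant(extra_s)], axis=0)
        if cfg.mi_inner_steps > 0:
            fit_critic(whole.data, sub.data, critic, cfg)
        loss = loss + cfg.lambda2 * mi_proxy_loss(whole, sub, critic, cfg)
    return r.prob, loss, r.Z
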