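"""MAML++-style meta-training across protein tasks.

Each protein defines one task: a class-balanced support set (k binding +
k nonbinding interactions) adapts the shared base model for a few inner
gradient steps, and a query set scores the adapted trajectory.  Following
MAML++, every inner step has its own learnable learning rate per parameter
layer (LSLR) and the outer objective is the importance-weighted sum of the
query losses after every inner step (multi-step loss, MSL), with the
importance weights annealed toward the final step over training.

Task contributions to the outer update are weighted by a task-adaptive
self-attention module: each task is embedded as the concatenation of its
protein pocket-subgraph embedding and the mean of its query molecule
embeddings; scaled dot-product self-attention over the batch followed by a
learnable scalar projection and a softmax yields per-task weights eta.

Meta-gradients are first order: inner-loop gradients are treated as
constants, so the outer gradient of a query loss lands directly on the
initial parameters (FOMAML) while still reaching the LSLR learning rates
through the linear update equations and the attention parameters through
eta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, constant, softmax
from .base_model import (ModelConfig, batched_task_forward, clone_params,
                         init_params, layer_key, make_molecule_batch,
                         zero_grads)
from .graphs import MoleculeGraph, ProteinGraph


# ---------------------------------------------------------------------------
# task containers
# ---------------------------------------------------------------------------

@dataclass
class TaskData:
    """All interactions of one protein, with resolved graphs."""
    protein: ProteinGraph
    molecules: list          # list[MoleculeGraph]
    labels: np.ndarray       # 0/1 per molecule


@dataclass
class Task:
    protein_id: str
    support_molecules: list
    support_labels: np.ndarray
    query_molecules: list
    query_labels: np.ndarray


class TaskSkip(Exception):
    """Raised when a protein lacks the records for a balanced task."""


def sample_task(task_data: dict[str, TaskData], protein_id: str,
                k: int = 5, m: int = 5, seed: int | None = None,
                rng=None) -> Task:
    """2-way k-shot support + m-query sample for one protein.

    Raises :class:`TaskSkip` if the protein lacks k binding, k nonbinding,
    or m leftover records.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    td = task_data[protein_id]
    pos = np.flatnonzero(td.labels == 1)
    neg = np.flatnonzero(td.labels == 0)
    if len(pos) < k or len(neg) < k or len(td.labels) < 2 * k + m:
        raise TaskSkip(f"{protein_id}: {len(pos)} pos / {len(neg)} neg "
                       f"insufficient for k={k}, m={m}")
    sup_pos = rng.choice(pos, size=k, replace=False)
    sup_neg = rng.choice(neg, size=k, replace=False)
    support = np.concatenate([sup_pos, sup_neg])
    rest = np.setdiff1d(np.arange(len(td.labels)), support)
    query = rng.choice(rest, size=m, replace=False)
    return Task(
        protein_id=protein_id,
        support_molecules=[td.molecules[i] for i in support],
        support_labels=td.labels[support],
        query_molecules=[td.molecules[i] for i in query],
        query_labels=td.labels[query],
    )


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass
class MetaConfig:
    inner_steps: int = 5
    meta_lr: float = 5e-3            # cosine-annealed to meta_lr_min
    meta_lr_min: float = 5e-4
    weight_decay: float = 1e-2       # outer-loop L2; discourages task memorization
    outer_steps: int = 300
    batch_size: int = 4
    k: int = 5                       # support shots per class
    m: int = 5                       # query size
    lslr_init: float = 0.01
    first_order: bool = True         # the only implemented order
    attention_enabled: bool = True   # False = uniform eta (ablation)
    outer_optimizer: str = "adam"    # 'adam' or 'sgd'
    msl_include_step_zero: bool = True   # query loss of the unadapted params
    msl_step_zero_weight: float | None = 0.5   # anchored mass on step 0
    msl_floor: float = 0.03          # minimum non-final step importance
    msl_anneal_frac: float = 0.6     # fraction of training to finish annealing
    warmup_frac: float = 0.5         # fraction of training with no inner loop
    n_restarts: int = 1              # short probe runs; best one continues
    restart_steps: int = 40          # probe length per restart
    polyak_tail: int = 0             # average params over the final K steps

    def upsilon(self, outer_step: int) -> np.ndarray:
        """Per-step importance weights over the query-loss trajectory.

        The multi-step loss runs from the unadapted parameters (step 0,
        which is what zero-shot inference uses) through every inner step,
        so the vector has ``inner_steps + 1`` entries when
        ``msl_include_step_zero`` is set.  With ``msl_step_zero_weight``
        set (the default), the unadapted step keeps that fixed mass and the
        rest spreads uniformly over the adapted steps — the zero-shot-first
        schedule.  With it ``None``, the MAML++ anneal applies: uniform at
        first, mass moving to the final step as training proceeds.
        """
        n = self.inner_steps + (1 if self.msl_include_step_zero else 0)
        if n == 1:
            return np.array([1.0])
        # warmup: gradient-based meta-learning is unstable from a random
        # initialization, so the first phase trains the shared predictor
        # without inner-loop adaptation (all mass on the unadapted step)
        if self.msl_include_step_zero and \
                outer_step < self.warmup_frac * self.outer_steps:
            return np.array([1.0])
        if self.msl_include_step_zero and self.msl_step_zero_weight is not None:
            a0 = float(self.msl_step_zero_weight)
            w = np.full(n, (1.0 - a0) / (n - 1))
            w[0] = a0
            return w
        total = max(1, int(self.msl_anneal_frac * self.outer_steps))
        t = min(1.0, outer_step / total)
        lo = self.msl_floor / n
        w = np.full(n, (1.0 - t) * (1.0 / n) + t * lo)
        w[-1] = 1.0 - w[:-1].sum()
        return w

    def alpha(self, outer_step: int) -> float:
        """Cosine-annealed meta learning rate."""
        t = min(1.0, outer_step / max(1, self.outer_steps))
        return self.meta_lr_min + 0.5 * (self.meta_lr - self.meta_lr_min) * (
            1.0 + math.cos(math.pi * t))


@dataclass
class MetaState:
    params: dict                     # base-model parameters (theta, phi1, cls)
    critic: dict                     # MI critic phi2 (outside outer descent)
    lslr: dict                       # (layer, step) -> Tensor scalar
    attention: dict                  # W_Q, W_K, W_V, w_out
    model_cfg: ModelConfig
    meta_cfg: MetaConfig
    history: list = field(default_factory=list)
    opt_state: dict = field(default_factory=dict)   # Adam moments
    opt_step: int = 0


def init_meta_state(model_cfg: ModelConfig, meta_cfg: MetaConfig,
                    seed: int = 0) -> MetaState:
    params, critic = init_params(model_cfg, seed=seed)
    layers = sorted({layer_key(name) for name in params})
    lslr = {(layer, step): Tensor(np.asarray(meta_cfg.lslr_init),
                                  requires_grad=True)
            for layer in layers for step in range(meta_cfg.inner_steps)}
    rng = np.random.default_rng(seed + 1)
    d_t = 2 * model_cfg.embed_dim      # [G_sub || mean G_m]
    s = 1.0 / np.sqrt(d_t)
    attention = {
        "W_Q": Tensor(rng.normal(0, s, (d_t, d_t)), requires_grad=True),
        "W_K": Tensor(rng.normal(0, s, (d_t, d_t)), requires_grad=True),
        "W_V": Tensor(rng.normal(0, s, (d_t, d_t)), requires_grad=True),
        # zero-init output projection: eta starts uniform and sharpens only
        # if the outer objective favors unequal task weighting
        "w_out": Tensor(np.zeros(d_t), requires_grad=True),
    }
    return MetaState(params=params, critic=critic, lslr=lslr,
                     attention=attention, model_cfg=model_cfg,
                     meta_cfg=meta_cfg)


def _trainable(state: MetaState) -> list[Tensor]:
    out = list(state.params.values()) + list(state.lslr.values())
    if state.meta_cfg.attention_enabled:
        out += list(state.attention.values())
    return out


# ---------------------------------------------------------------------------
# inner loop
# ---------------------------------------------------------------------------

def _support_gradients(params_at: dict, protein, mol_batch, labels, state,
                       rng, fit_critic_now: bool = True) -> tuple[dict, float]:
    """Numeric gradient of the support loss at the given parameter values."""
    leaves = {k: Tensor(v.data, requires_grad=True) for k, v in params_at.items()}
    loss, _, _, _ = batched_task_forward(protein, mol_batch, labels, leaves,
                                         state.critic, state.model_cfg, rng=rng,
                                         fit_critic_now=fit_critic_now)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite support loss {loss.data}")
    loss.backward()
    grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.data))
             for k, t in leaves.items()}
    return grads, loss.item()


def inner_adapt(state: MetaState, protein: ProteinGraph, molecules: list,
                labels, n_steps: int | None = None, rng=None):
    """Adapt the base parameters on a support set.

    Returns ``(trajectory, support_losses)`` where ``trajectory[i]`` is the
    parameter dict after ``i + 1`` inner steps.  Each update is
    ``theta <- theta - lr(layer, step) * grad`` with the per-layer per-step
    LSLR rates; gradients are constants (first order), so the trajectory
    tensors remain differentiable w.r.t. the initial parameters and the
    rates.
    """
    cfg = state.meta_cfg
    n_steps = cfg.inner_steps if n_steps is None else n_steps
    rng = rng or np.random.default_rng(0)
    mol_batch = make_molecule_batch(molecules, state.model_cfg)
    current = dict(state.params)
    trajectory, support_losses = [], []
    for step in range(n_steps):
        # critic ascent once per task: refreshing at every forward is
        # available via batched_task_forward(fit_critic_now=...), but one
        # refresh per task keeps the desk-scale budget (see methods note)
        grads, sup_loss = _support_gradients(current, protein, mol_batch,
                                             labels, state, rng,
                                             fit_critic_now=step == 0)
        support_losses.append(sup_loss)
        current = {name: current[name] - state.lslr[(layer_key(name), step)]
                   * constant(grads[name])
                   for name in current}
        trajectory.append(current)
    return trajectory, support_losses


def multi_step_query_loss(state: MetaState, trajectory: list, protein,
                          molecules, labels, upsilon, rng=None,
                          fit_critic_first: bool = False):
    """``sum_i upsilon_i * L_query(theta_i)`` over the adapted trajectory.

    Returns ``(loss, last_results)`` with the final step's forward results
    (used for the task embedding).
    """
    if len(trajectory) != len(upsilon):
        raise ValueError(f"{len(trajectory)} adapted sets vs {len(upsilon)} weights")
    rng = rng or np.random.default_rng(0)
    mol_batch = make_molecule_batch(molecules, state.model_cfg)
    total, last_aux = None, None
    for i, (params_i, u) in enumerate(zip(trajectory, upsilon)):
        loss_i, _, _, aux = batched_task_forward(protein, mol_batch, labels,
                                                 params_i, state.critic,
                                                 state.model_cfg, rng=rng,
                                                 fit_critic_now=(
                                                     fit_critic_first and i == 0))
        term = float(u) * loss_i
        total = term if total is None else total + term
        last_aux = aux
    return total, last_aux


# ---------------------------------------------------------------------------
# task-adaptive self-attention
# ---------------------------------------------------------------------------

def task_weights(task_embeds: Tensor, attention: dict) -> Tensor:
    """Per-task importance eta: nonnegative, sums to 1 over the batch.

    ``task_embeds`` is (B, d_t).  Q/K/V are linear maps of the embeddings,
    scaled dot-product attention mixes the batch, and a learnable scalar
    projection followed by a batch softmax produces eta.
    """
    b = task_embeds.shape[0]
    if b == 0:
        raise ValueError("empty task batch")
    q = task_embeds @ attention["W_Q"]
    k = task_embeds @ attention["W_K"]
    v = task_embeds @ attention["W_V"]
    d_k = q.shape[1]
    att = softmax(q @ k.T * (1.0 / np.sqrt(d_k)), axis=1) @ v
    scores = att @ attention["w_out"]
    return softmax(scores, axis=0)


def _task_embedding(aux) -> Tensor:
    """[mean pocket-subgraph embedding || mean query molecule embedding]."""
    return concat([aux.sub_embeds.mean(axis=0),
                   aux.mol_embeds.mean(axis=0)], axis=0)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def meta_step(state: MetaState, tasks: list[Task],
              task_data: dict[str, TaskData], outer_step: int = 0,
              rng=None) -> dict:
    """One outer update over a batch of tasks; returns a log record."""
    if not tasks:
        raise ValueError("empty task batch")
    cfg = state.meta_cfg
    rng = rng or np.random.default_rng(0)
    upsilon = cfg.upsilon(outer_step)

    for t in _trainable(state):
        t.grad = None
    zero_grads(state.params)

    n_inner = len(upsilon) - (1 if cfg.msl_include_step_zero else 0)
    query_losses, embeds = [], []
    for task in tasks:
        protein = task_data[task.protein_id].protein
        trajectory, _ = inner_adapt(state, protein, task.support_molecules,
                                    task.support_labels, n_steps=n_inner,
                                    rng=rng)
        if cfg.msl_include_step_zero:
            trajectory = [dict(state.params)] + trajectory
        q_loss, aux = multi_step_query_loss(
            state, trajectory, protein, task.query_molecules,
            task.query_labels, upsilon, rng=rng,
            fit_critic_first=n_inner == 0)
        query_losses.append(q_loss)
        embeds.append(_task_embedding(aux))

    # task-adaptive weighting belongs to the meta phase; during warmup
    # (single-entry upsilon, no inner loop) tasks weigh uniformly
    if cfg.attention_enabled and len(tasks) > 1 and len(upsilon) > 1:
        eta = task_weights(concat([e.reshape(1, -1) for e in embeds], axis=0),
                           state.attention)
        weighted = [eta[i] * query_losses[i] for i in range(len(tasks))]
        l_all = sum(weighted[1:], weighted[0])
        eta_vals = eta.data.copy()
    else:
        w = 1.0 / len(tasks)
        scaled = [w * q for q in query_losses]
        l_all = sum(scaled[1:], scaled[0])
        eta_vals = np.full(len(tasks), w)

    if not np.isfinite(l_all.data):
        raise FloatingPointError(
            f"non-finite meta loss for tasks {[t.protein_id for t in tasks]}")
    l_all.backward()

    alpha = cfg.alpha(outer_step)
    state.opt_step += 1
    decayed = set(id(t) for t in state.params.values())
    for i, t in enumerate(_trainable(state)):
        if t.grad is None:
            continue
        g = t.grad
        if cfg.outer_optimizer == "adam":
            m, v = state.opt_state.setdefault(
                i, (np.zeros_like(t.data), np.zeros_like(t.data)))
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            state.opt_state[i] = (m, v)
            mh = m / (1.0 - 0.9 ** state.opt_step)
            vh = v / (1.0 - 0.999 ** state.opt_step)
            g = mh / (np.sqrt(vh) + 1e-8)
        if id(t) in decayed:        # lslr and attention: no decay
            g = g + cfg.weight_decay * t.data
        t.data = t.data - alpha * g
        t.grad = None

    record = {"outer_step": outer_step, "loss": float(l_all.data),
              "alpha": alpha, "eta": eta_vals,
              "tasks": [t.protein_id for t in tasks]}
    state.history.append(record)
    return record


def _run_steps(state: MetaState, task_data: dict, rng, start: int, n_steps: int,
               verbose: bool = False) -> None:
    cfg = state.meta_cfg
    eligible = sorted(task_data)
    tail_sum, tail_n = None, 0
    tail_from = start + n_steps - cfg.polyak_tail
    for step in range(start, start + n_steps):
        tasks = []
        guard = 0
        while len(tasks) < cfg.batch_size and guard < 10 * cfg.batch_size:
            pid = eligible[rng.integers(len(eligible))]
            guard += 1
            try:
                tasks.append(sample_task(task_data, pid, k=cfg.k, m=cfg.m,
                                         rng=rng))
            except TaskSkip:
                continue
        if not tasks:
            raise RuntimeError("no protein has enough records for a task")
        rec = meta_step(state, tasks, task_data, outer_step=step, rng=rng)
        if cfg.polyak_tail > 0 and step >= tail_from:
            if tail_sum is None:
                tail_sum = {k: v.data.copy() for k, v in state.params.items()}
            else:
                for k, v in state.params.items():
                    tail_sum[k] += v.data
            tail_n += 1
        if verbose and step % 20 == 0:
            print(f"[meta] step {step:4d} loss {rec['loss']:.4f} "
                  f"alpha {rec['alpha']:.2e}")
    if tail_n > 0:   # Polyak tail average stabilizes the final iterate
        for k, v in state.params.items():
            v.data = tail_sum[k] / tail_n


def _train_side_auroc(state: MetaState, task_data: dict,
                      max_proteins: int = 20) -> float:
    """Zero-shot AUROC pooled over training tasks (model selection only —
    never touches held-out data)."""
    from .evaluation import auroc as _auroc
    labels, scores = [], []
    for pid in sorted(task_data)[:max_proteins]:
        td = task_data[pid]
        probs, _ = predict_zero_shot(state, td.protein, td.molecules)
        labels += list(td.labels)
        scores += list(probs)
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        return 0.5
    return _auroc(labels, scores)


def meta_train(task_data: dict[str, TaskData], model_cfg: ModelConfig,
               meta_cfg: MetaConfig, seed: int = 0,
               verbose: bool = False) -> MetaState:
    """Full meta-training loop over the provided protein tasks.

    With ``n_restarts > 1``, several short probe runs start from different
    initializations and the one with the best training-side zero-shot AUROC
    continues; the probes count against the outer-step budget, so the total
    number of outer updates never exceeds ``outer_steps``.
    """
    n_probe = meta_cfg.n_restarts if meta_cfg.n_restarts > 1 else 0
    probe_cost = n_probe * meta_cfg.restart_steps
    if probe_cost >= meta_cfg.outer_steps:
        raise ValueError("restart probes exhaust the outer-step budget")

    if n_probe == 0:
        state = init_meta_state(model_cfg, meta_cfg, seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        _run_steps(state, task_data, rng, 0, meta_cfg.outer_steps,
                   verbose=verbose)
        return state

    candidates = []
    for r in range(n_probe):
        state = init_meta_state(model_cfg, meta_cfg, seed=seed + 101 * r)
        rng = np.random.default_rng(seed + 10_000 + 977 * r)
        _run_steps(state, task_data, rng, 0, meta_cfg.restart_steps)
        candidates.append((state, rng, _train_side_auroc(state, task_data)))
    state, rng, _ = max(candidates, key=lambda c: c[2])
    # continue on the tail of the global schedule so the winner still
    # traverses the warmup -> meta transition and the full lr anneal
    remaining = meta_cfg.outer_steps - probe_cost
    _run_steps(state, task_data, rng, meta_cfg.outer_steps - remaining,
               remaining, verbose=verbose)
    return state


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_zero_shot(state: MetaState, protein: ProteinGraph,
                      molecules: list[MoleculeGraph], params: dict | None = None):
    """Probabilities (and assignment matrices) under the meta parameters,
    without any adaptation.  Deterministic given the parameters."""
    params = state.params if params is None else params
    mol_batch = make_molecule_batch(molecules, state.model_cfg)
    rng = np.random.default_rng(0)   # only used by the random-Z ablation
    _, probs, z_stack, _ = batched_task_forward(
        protein, mol_batch, np.zeros(len(molecules)), params, state.critic,
        state.model_cfg, rng=rng, train=False)
    zs = None if z_stack is None else [z_stack[i] for i in range(len(molecules))]
    return probs.data.copy(), zs


def fine_tune(state: MetaState, protein: ProteinGraph, molecules: list,
              labels, steps: int = 20, lr: float = 0.01,
              seed: int = 0) -> dict:
    """Protein-specific parameters: plain gradient descent of the base loss
    on the fine-tune records starting from the meta initialization.  The
    meta parameters are left untouched."""
    params = clone_params(state.params)
    labels = np.asarray(labels)
    mol_batch = make_molecule_batch(molecules, state.model_cfg)
    rng = np.random.default_rng(seed)
    for _ in range(steps):
        zero_grads(params)
        loss, _, _, _ = batched_task_forward(protein, mol_batch, labels, params,
                                             state.critic, state.model_cfg,
                                             rng=rng)
        loss.backward()
        for t in params.values():
            if t.grad is not None:
                t.data = t.data - lr * t.grad
                t.grad = None
    return params


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: MetaState, path) -> None:
    """Single-container checkpoint with named parameter groups."""
    import json

    def grp(d):
        return {k if isinstance(k, str) else f"{k[0]}|{k[1]}": v.data.tolist()
                for k, v in d.items()}

    payload = {
        "format": "metabind-checkpoint", "version": 1,
        "model_cfg": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in vars(state.model_cfg).items()},
        "meta_cfg": vars(state.meta_cfg),
        "params": grp(state.params), "critic": grp(state.critic),
        "lslr": grp(state.lslr), "attention": grp(state.attention),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> MetaState:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    model_cfg = ModelConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                               for k, v in payload["model_cfg"].items()})
    meta_cfg = MetaConfig(**payload["meta_cfg"])
    state = init_meta_state(model_cfg, meta_cfg, seed=0)

    def setgrp(dst, src, tuple_keys=False):
        for k, v in src.items():
            key = k
            if tuple_keys:
                layer, step = k.rsplit("|", 1)
                key = (layer, int(step))
            dst[key] = Tensor(np.asarray(v), requires_grad=True)

    setgrp(state.params, payload["params"])
    setgrp(state.critic, payload["critic"])
    setgrp(state.lslr, payload["lslr"], tuple_keys=True)
    setgrp(state.attention, payload["attention"])
    return state
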