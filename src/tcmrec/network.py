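"""Scene-conditioned multi-task meta-attention network and baselines.

The main model scores evidence elements for the five category tasks
(a = disease site, b = essential substance, c = disease evil,
d = pathological state, e = connecting word).  Pipeline::

    token embeddings -> multi-head self-attention + position-wise FFN
    (high-order symptom features) -> squeeze-and-excitation fusion with
    patient, context and dense statistical feature blocks -> expert group
    (S shared + K-per-task unique FFN experts) -> per-task meta-attention
    gate -> per-task meta tower -> per-task element logits

A *meta unit* is a dense ReLU layer whose weight matrix and bias are
generated from a scene embedding (an affine map reshaped into the layer's
parameters), so effective parameters vary by scene.  *Meta attention*
scores each expert output through a meta unit and a projection vector,
softmax-normalised over the S+K experts visible to the task.  By default
the conditioning scene is the task identity (a learned per-task
embedding); ``scene_field`` can route a per-case categorical (department
or season) instead, in which case generated weights are batched.

The squeeze-and-excitation fusion is additive by default
(``x_{l+1} = x_l + s``, with ``s = σ(MLP(z))``); ``senet_mode =
"multiplicative"`` selects the canonical re-weighting ``x ⊙ s``.  The
position-wise feed-forward layer computes ``ReLU((xW1+b1)W2)+b2`` with
the rectifier outside the second product.

Baselines: an MLP over the same encoded inputs with five heads, and an
MMoE with a plain softmax gate per task over shared experts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, embedding, stack

TASK_CODES = ("a", "b", "c", "d", "e")


@dataclass
class ModelConfig:
    embed_dim: int = 32            # d; shared by symptom/profile embeddings
    n_heads: int = 2               # h; must divide embed_dim
    ffn_hidden: int | None = None  # d_k; default d*h
    n_shared_experts: int = 2      # S
    n_unique_experts: int = 1      # K per task
    n_tasks: int = 5
    expert_hidden: int = 96
    expert_dim: int = 64
    tower_depth: int = 2
    tower_hidden: int = 64
    scene_dim: int = 8
    scene_field: str = "task"      # "task" | "department" | "season"
    meta_hidden: int = 8           # meta-attention meta-unit output width
    senet_hidden: int = 8
    senet_mode: str = "additive"   # "additive" | "multiplicative"
    merge: str = "sigmoid"         # global ranking merge: "sigmoid" | "softmax"
    mlp_hidden: tuple[int, ...] = (128, 64)
    wide_path: bool = True         # add association-evidence score to task heads
    head_init_scale: float = 0.1   # deep head starts as a small wide-path correction
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim <= 0 or self.n_heads <= 0:
            raise ValueError("embed_dim and n_heads must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide embed_dim={self.embed_dim}")
        if self.ffn_hidden is None:
            self.ffn_hidden = self.embed_dim * self.n_heads
        if self.senet_mode not in ("additive", "multiplicative"):
            raise ValueError(f"bad senet_mode {self.senet_mode!r}")
        if self.scene_field not in ("task", "department", "season"):
            raise ValueError(f"bad scene_field {self.scene_field!r}")


@dataclass
class EmbeddedBatch:
    """Concatenated embedding blocks: patient, context, scene, dense."""

    e_u: Tensor          # (B, d)    patient profile block
    e_i: Tensor          # (B, T, d) symptom-token sequence (context/medicine block)
    e_s: Tensor          # (B, scene_dim) scene block
    dense: Tensor        # (B, n_dense) raw dense statistics
    mask: np.ndarray     # (B, T) 1.0 for real tokens

    @property
    def concatenated(self) -> Tensor:
        pooled = masked_mean(self.e_i, self.mask)
        return concat([self.e_u, pooled, self.e_s, self.dense], axis=-1)


# -- initializers ---------------------------------------------------------

def trunc_normal(rng, shape, sigma=0.05):
    x = rng.normal(0.0, sigma, size=shape)
    return np.clip(x, -2 * sigma, 2 * sigma)


def dense_init(rng, fan_in, fan_out):
    return rng.normal(0.0, 1.0 / math.sqrt(max(fan_in, 1)), size=(fan_in, fan_out))


# -- functional pieces ----------------------------------------------------

def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over axis 1 ignoring padded positions (mask rows never all-zero)."""
    m = mask[:, :, None]
    denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor,
                         mask_bias: np.ndarray | None = None) -> Tensor:
    """softmax(Q Kᵀ / √d) V, d = key dimension; rows sum to one."""
    d = Q.shape[-1]
    if d == 0:
        raise ValueError("attention dimension must be positive")
    axes = tuple(range(K.ndim - 2)) + (K.ndim - 1, K.ndim - 2)
    scores = (Q @ K.transpose(axes)) * (1.0 / math.sqrt(d))
    if mask_bias is not None:
        scores = scores + Tensor(mask_bias)
    return scores.softmax(axis=-1) @ V


def feed_forward(x: Tensor, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor) -> Tensor:
    """ReLU((xW1 + b1) W2) + b2 — rectifier outside the second product."""
    return ((x @ W1 + b1) @ W2).relu() + b2


def meta_unit(x: Tensor, scene_emb: Tensor, Wg: Tensor, bg: Tensor,
              in_dim: int, out_dim: int, activation: bool = True) -> Tensor:
    """Dense layer whose (W, b) are generated from the scene embedding.

    ``scene_emb`` of shape (scene_dim,) yields one weight set shared by the
    batch; shape (B, scene_dim) yields per-sample generated weights.
    """
    gen = scene_emb @ Wg + bg  # (.., in*out + out)
    if gen.shape[-1] != in_dim * out_dim + out_dim:
        raise ValueError(
            f"meta generator emits {gen.shape[-1]} values, layer needs "
            f"{in_dim * out_dim + out_dim}")
    if gen.ndim == 1:
        W = gen[:in_dim * out_dim].reshape(out_dim, in_dim)
        b = gen[in_dim * out_dim:]
        y = x @ W.transpose(1, 0) + b
    else:
        B = gen.shape[0]
        W = gen[:, :in_dim * out_dim].reshape(B, out_dim, in_dim)
        b = gen[:, in_dim * out_dim:]
        y = (W @ x.reshape(B, in_dim, 1)).reshape(B, out_dim) + b
    return y.relu() if activation else y


def senet_fuse(groups: list[Tensor], W1: Tensor, b1: Tensor, W2: Tensor,
               b2: Tensor, mode: str = "additive") -> Tensor:
    """Squeeze-and-excitation fusion of feature groups.

    Squeeze: per-group means -> excitation MLP -> sigmoid gate ``s`` with
    the length of the concatenated representation; additive output
    ``x + s`` (default) or multiplicative ``x ⊙ s``.
    """
    if not groups:
        raise ValueError("senet_fuse: no feature groups")
    x = concat(groups, axis=-1)
    z = concat([g.mean(axis=-1, keepdims=True) for g in groups], axis=-1)
    s = (((z @ W1 + b1).relu()) @ W2 + b2).sigmoid()
    return x + s if mode == "additive" else x * s


def _wide_term(params, cfg: ModelConfig, task: int, logits_t: Tensor,
               batch: dict) -> Tensor:
    """Wide path: association-evidence scores enter the head additively."""
    if not cfg.wide_path:
        return logits_t
    wide = batch.get("wide")
    if wide is None:
        raise ValueError("wide_path enabled but batch carries no 'wide' features")
    return logits_t + Tensor(wide[task]) * params[f"wide{task}_a"]


# -- the main model -------------------------------------------------------

class MetaAttentionNet:
    """Multi-task meta-attention recommender (see module docstring)."""

    kind = "meta"

    def __init__(self, config: ModelConfig, sizes: dict):
        """``sizes``: n_symptom_ids, n_profile_ids, n_scene_ids, dense_dim,
        task_vocab_sizes (list of 5)."""
        self.config = config
        self.sizes = dict(sizes)
        cfg = config
        if len(sizes["task_vocab_sizes"]) != cfg.n_tasks:
            raise ValueError("task_vocab_sizes must have one entry per task")
        rng = np.random.default_rng(cfg.seed)
        d, dk = cfg.embed_dim, cfg.ffn_hidden
        P: dict[str, Tensor] = {}

        def par(name, arr):
            P[name] = Tensor(arr, requires_grad=True, name=name)
            return P[name]

        par("E_sym", trunc_normal(rng, (sizes["n_symptom_ids"], d)))
        par("E_prof", trunc_normal(rng, (sizes["n_profile_ids"], d)))
        par("E_scene", trunc_normal(rng, (sizes["n_scene_ids"], cfg.scene_dim)))
        par("E_task_scene", trunc_normal(rng, (cfg.n_tasks, cfg.scene_dim)))
        for nm in ("Wq", "Wk", "Wv", "WH"):
            par(nm, dense_init(rng, d, d))
        par("ffn_W1", dense_init(rng, d, dk)); par("ffn_b1", np.zeros(dk))
        par("ffn_W2", dense_init(rng, dk, d)); par("ffn_b2", np.zeros(d))
        par("Wd", dense_init(rng, sizes["dense_dim"], d)); par("bd", np.zeros(d))
        self.fused_dim = 3 * d + cfg.scene_dim
        n_groups = 4
        par("sen_W1", dense_init(rng, n_groups, cfg.senet_hidden))
        par("sen_b1", np.zeros(cfg.senet_hidden))
        par("sen_W2", dense_init(rng, cfg.senet_hidden, self.fused_dim))
        par("sen_b2", np.zeros(self.fused_dim))
        self.n_experts = cfg.n_shared_experts + cfg.n_unique_experts * cfg.n_tasks
        for i in range(self.n_experts):
            par(f"exp{i}_W1", dense_init(rng, self.fused_dim, cfg.expert_hidden))
            par(f"exp{i}_b1", np.zeros(cfg.expert_hidden))
            par(f"exp{i}_W2", dense_init(rng, cfg.expert_hidden, cfg.expert_dim))
            par(f"exp{i}_b2", np.zeros(cfg.expert_dim))
        for t in range(cfg.n_tasks):
            self._init_meta_generator(par, rng, f"gate{t}",
                                      cfg.expert_dim, cfg.meta_hidden)
            par(f"gate{t}_V", rng.normal(0, 1.0 / math.sqrt(cfg.meta_hidden),
                                         size=cfg.meta_hidden))
            dims = [cfg.expert_dim] + [cfg.tower_hidden] * cfg.tower_depth
            for l in range(cfg.tower_depth):
                self._init_meta_generator(par, rng, f"tower{t}_{l}",
                                          dims[l], dims[l + 1])
            vt = sizes["task_vocab_sizes"][t]
            par(f"head{t}_W", dense_init(rng, dims[-1], vt) * cfg.head_init_scale)
            par(f"head{t}_b", np.zeros(vt))
            if cfg.wide_path:
                par(f"wide{t}_a", np.ones(1))
        self._params = P

    def _init_meta_generator(self, par, rng, name, in_dim, out_dim):
        """Generator affine map; its bias holds a fan-in-scaled base layer so the
        scene modulation starts as a small perturbation of a plain dense layer."""
        L = in_dim * out_dim + out_dim
        par(f"{name}_Wg", rng.normal(0, 0.05 / math.sqrt(self.config.scene_dim),
                                     size=(self.config.scene_dim, L)))
        base_W = rng.normal(0, 1.0 / math.sqrt(in_dim), size=(out_dim, in_dim))
        par(f"{name}_bg", np.concatenate([base_W.ravel(), np.zeros(out_dim)]))

    # -----------------------------------------------------------------
    def params(self) -> dict[str, Tensor]:
        return self._params

    def zero_grad(self):
        for p in self._params.values():
            p.zero_grad()

    def _meta_scene(self, task: int, batch: dict) -> Tensor:
        """Conditioning scene for meta units: task embedding (default) or the
        per-case scene embedding when ``scene_field`` is a case field."""
        P = self._params
        if self.config.scene_field == "task":
            return embedding(P["E_task_scene"], np.array(task))
        ids = batch.get("meta_scene_ids", batch["scene_ids"])
        return embedding(P["E_scene"], ids)

    def embed_batch(self, batch: dict) -> EmbeddedBatch:
        P = self._params
        sym_ids = batch["sym_ids"]
        mask = batch.get("mask")
        if mask is None:
            mask = (sym_ids > 0).astype(float)
        e_i = embedding(P["E_sym"], sym_ids)                       # (B,T,d)
        prof_ids = batch["prof_ids"]
        prof_mask = (prof_ids > 0).astype(float)
        e_u = masked_mean(embedding(P["E_prof"], prof_ids), prof_mask)
        e_s = embedding(P["E_scene"], batch["scene_ids"])
        return EmbeddedBatch(e_u=e_u, e_i=e_i, e_s=e_s,
                             dense=Tensor(batch["dense"]), mask=mask)

    def multi_head_block(self, X: Tensor, mask: np.ndarray) -> Tensor:
        cfg, P = self.config, self._params
        d, h = cfg.embed_dim, cfg.n_heads
        dh = d // h
        Q, K, V = X @ P["Wq"], X @ P["Wk"], X @ P["Wv"]
        bias = np.where(mask[:, None, :] > 0, 0.0, -1e9)  # (B,1,T)
        heads = []
        for i in range(h):
            sl = slice(i * dh, (i + 1) * dh)
            heads.append(scaled_dot_attention(Q[:, :, sl], K[:, :, sl],
                                              V[:, :, sl], mask_bias=bias))
        return concat(heads, axis=-1) @ P["WH"]

    def _expert(self, i: int, fused: Tensor) -> Tensor:
        P = self._params
        h = (fused @ P[f"exp{i}_W1"] + P[f"exp{i}_b1"]).relu()
        return (h @ P[f"exp{i}_W2"] + P[f"exp{i}_b2"]).relu()

    def meta_attention(self, expert_outs: list[Tensor], scene_emb: Tensor,
                       task: int) -> Tensor:
        """Softmax gate over the task's visible experts; (B, n_experts)."""
        cfg, P = self.config, self._params
        scores = []
        for E in expert_outs:
            m = meta_unit(E, scene_emb, P[f"gate{task}_Wg"], P[f"gate{task}_bg"],
                          cfg.expert_dim, cfg.meta_hidden)
            scores.append(m @ P[f"gate{task}_V"])  # (B,)
        return stack(scores, axis=1).softmax(axis=1)

    def meta_tower(self, x: Tensor, scene_emb: Tensor, task: int) -> Tensor:
        cfg, P = self.config, self._params
        dims = [cfg.expert_dim] + [cfg.tower_hidden] * cfg.tower_depth
        h = x
        for l in range(cfg.tower_depth):
            h = meta_unit(h, scene_emb, P[f"tower{task}_{l}_Wg"],
                          P[f"tower{task}_{l}_bg"], dims[l], dims[l + 1])
        return h @ P[f"head{task}_W"] + P[f"head{task}_b"]

    def forward(self, batch: dict) -> list[Tensor]:
        """Per-task logits, one (B, V_t) tensor per category task."""
        cfg, P = self.config, self._params
        eb = self.embed_batch(batch)
        S_out = self.multi_head_block(eb.e_i, eb.mask)
        high = feed_forward(S_out, P["ffn_W1"], P["ffn_b1"],
                            P["ffn_W2"], P["ffn_b2"])       # (B,T,d)
        pooled = masked_mean(high, eb.mask)                  # (B,d)
        dense_p = (eb.dense @ P["Wd"] + P["bd"]).relu()
        fused = senet_fuse([eb.e_u, pooled, eb.e_s, dense_p],
                           P["sen_W1"], P["sen_b1"], P["sen_W2"], P["sen_b2"],
                           mode=cfg.senet_mode)
        expert_outs = [self._expert(i, fused) for i in range(self.n_experts)]
        S = cfg.n_shared_experts
        logits = []
        for t in range(cfg.n_tasks):
            mine = expert_outs[:S] + expert_outs[
                S + t * cfg.n_unique_experts: S + (t + 1) * cfg.n_unique_experts]
            scene_emb = self._meta_scene(t, batch)
            alpha = self.meta_attention(mine, scene_emb, t)  # (B, S+K)
            gated = None
            for i, E in enumerate(mine):
                term = alpha[:, i:i + 1] * E
                gated = term if gated is None else gated + term
            logits.append(_wide_term(P, cfg, t,
                                     self.meta_tower(gated, scene_emb, t), batch))
        return logits

    # -- scene-independent limit --------------------------------------
    def zero_meta_generators(self):
        """Zero every meta-generator weight: all meta units collapse to the
        fixed dense layers stored in their generator biases."""
        for name, p in self._params.items():
            if name.endswith("_Wg"):
                p.data[:] = 0.0


def degenerate_numpy_forward(model: MetaAttentionNet, batch: dict) -> list[np.ndarray]:
    """Plain-numpy forward of the scene-independent limit.

    An independently written MMoE-like pipeline: every meta unit is read as
    the fixed dense layer held in its generator bias, gates are fixed
    softmax scores, towers are plain dense stacks.  Valid (and compared in
    tests) only after :meth:`MetaAttentionNet.zero_meta_generators`.
    """
    cfg = model.config
    P = {k: v.data for k, v in model.params().items()}
    sym_ids, prof_ids = batch["sym_ids"], batch["prof_ids"]
    mask = (sym_ids > 0).astype(float)
    X = P["E_sym"][sym_ids]
    d, h = cfg.embed_dim, cfg.n_heads
    dh = d // h
    Q, K, V = X @ P["Wq"], X @ P["Wk"], X @ P["Wv"]
    heads = []
    bias = np.where(mask[:, None, :] > 0, 0.0, -1e9)
    for i in range(h):
        sl = slice(i * dh, (i + 1) * dh)
        sc = Q[:, :, sl] @ K[:, :, sl].transpose(0, 2, 1) / math.sqrt(dh) + bias
        sc -= sc.max(axis=-1, keepdims=True)
        A = np.exp(sc)
        A /= A.sum(axis=-1, keepdims=True)
        heads.append(A @ V[:, :, sl])
    S_out = np.concatenate(heads, axis=-1) @ P["WH"]
    high = np.maximum((S_out @ P["ffn_W1"] + P["ffn_b1"]) @ P["ffn_W2"], 0) + P["ffn_b2"]

    def mmean(x, m):
        return (x * m[:, :, None]).sum(1) / np.maximum(m.sum(1, keepdims=True), 1)

    pooled = mmean(high, mask)
    pm = (prof_ids > 0).astype(float)
    e_u = mmean(P["E_prof"][prof_ids], pm)
    e_s = P["E_scene"][batch["scene_ids"]]
    dense_p = np.maximum(batch["dense"] @ P["Wd"] + P["bd"], 0)
    groups = [e_u, pooled, e_s, dense_p]
    x = np.concatenate(groups, axis=-1)
    z = np.stack([g.mean(axis=-1) for g in groups], axis=-1)
    gate = 1 / (1 + np.exp(-(np.maximum(z @ P["sen_W1"] + P["sen_b1"], 0)
                             @ P["sen_W2"] + P["sen_b2"])))
    fused = x + gate if cfg.senet_mode == "additive" else x * gate
    experts = []
    for i in range(model.n_experts):
        hdn = np.maximum(fused @ P[f"exp{i}_W1"] + P[f"exp{i}_b1"], 0)
        experts.append(np.maximum(hdn @ P[f"exp{i}_W2"] + P[f"exp{i}_b2"], 0))

    def fixed_dense(name, x_, in_dim, out_dim, act=True):
        gen = P[f"{name}_bg"]
        W = gen[:in_dim * out_dim].reshape(out_dim, in_dim)
        b = gen[in_dim * out_dim:]
        y = x_ @ W.T + b
        return np.maximum(y, 0) if act else y

    out = []
    S = cfg.n_shared_experts
    for t in range(cfg.n_tasks):
        mine = experts[:S] + experts[S + t * cfg.n_unique_experts:
                                     S + (t + 1) * cfg.n_unique_experts]
        scores = np.stack([
            fixed_dense(f"gate{t}", E, cfg.expert_dim, cfg.meta_hidden)
            @ P[f"gate{t}_V"] for E in mine], axis=1)
        scores -= scores.max(axis=1, keepdims=True)
        alpha = np.exp(scores)
        alpha /= alpha.sum(axis=1, keepdims=True)
        gated = sum(alpha[:, i:i + 1] * E for i, E in enumerate(mine))
        dims = [cfg.expert_dim] + [cfg.tower_hidden] * cfg.tower_depth
        hdn = gated
        for l in range(cfg.tower_depth):
            hdn = fixed_dense(f"tower{t}_{l}", hdn, dims[l], dims[l + 1])
        z = hdn @ P[f"head{t}_W"] + P[f"head{t}_b"]
        if cfg.wide_path:
            z = z + batch["wide"][t] * P[f"wide{t}_a"]
        out.append(z)
    return out


# -- baselines ------------------------------------------------------------

class MLPNet:
    """Embeddings + stacked dense ReLU + five heads over the same inputs."""

    kind = "mlp"

    def __init__(self, config: ModelConfig, sizes: dict):
        self.config = config
        self.sizes = dict(sizes)
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        P: dict[str, Tensor] = {}

        def par(name, arr):
            P[name] = Tensor(arr, requires_grad=True, name=name)

        par("E_sym", trunc_normal(rng, (sizes["n_symptom_ids"], d)))
        par("E_prof", trunc_normal(rng, (sizes["n_profile_ids"], d)))
        par("E_scene", trunc_normal(rng, (sizes["n_scene_ids"], config.scene_dim)))
        par("Wd", dense_init(rng, sizes["dense_dim"], d)); par("bd", np.zeros(d))
        in_dim = 3 * d + config.scene_dim
        dims = [in_dim, *config.mlp_hidden]
        for l in range(len(dims) - 1):
            par(f"h{l}_W", dense_init(rng, dims[l], dims[l + 1]))
            par(f"h{l}_b", np.zeros(dims[l + 1]))
        for t, vt in enumerate(sizes["task_vocab_sizes"]):
            par(f"head{t}_W", dense_init(rng, dims[-1], vt) * config.head_init_scale)
            par(f"head{t}_b", np.zeros(vt))
            if config.wide_path:
                par(f"wide{t}_a", np.ones(1))
        self._params = P
        self.n_hidden = len(dims) - 1

    def params(self):
        return self._params

    def zero_grad(self):
        for p in self._params.values():
            p.zero_grad()

    def _encode(self, batch: dict) -> Tensor:
        P = self._params
        sym_ids = batch["sym_ids"]
        mask = (sym_ids > 0).astype(float)
        pooled = masked_mean(embedding(P["E_sym"], sym_ids), mask)
        pm = (batch["prof_ids"] > 0).astype(float)
        e_u = masked_mean(embedding(P["E_prof"], batch["prof_ids"]), pm)
        e_s = embedding(P["E_scene"], batch["scene_ids"])
        dense_p = (Tensor(batch["dense"]) @ P["Wd"] + P["bd"]).relu()
        return concat([e_u, pooled, e_s, dense_p], axis=-1)

    def forward(self, batch: dict) -> list[Tensor]:
        P = self._params
        hdn = self._encode(batch)
        for l in range(self.n_hidden):
            hdn = (hdn @ P[f"h{l}_W"] + P[f"h{l}_b"]).relu()
        return [_wide_term(P, self.config, t,
                           hdn @ P[f"head{t}_W"] + P[f"head{t}_b"], batch)
                for t in range(self.config.n_tasks)]


class MMoENet:
    """Shared experts with plain per-task softmax gates and dense towers."""

    kind = "mmoe"

    def __init__(self, config: ModelConfig, sizes: dict):
        self.config = config
        self.sizes = dict(sizes)
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        P: dict[str, Tensor] = {}

        def par(name, arr):
            P[name] = Tensor(arr, requires_grad=True, name=name)

        par("E_sym", trunc_normal(rng, (sizes["n_symptom_ids"], d)))
        par("E_prof", trunc_normal(rng, (sizes["n_profile_ids"], d)))
        par("E_scene", trunc_normal(rng, (sizes["n_scene_ids"], config.scene_dim)))
        par("Wd", dense_init(rng, sizes["dense_dim"], d)); par("bd", np.zeros(d))
        in_dim = 3 * d + config.scene_dim
        self.n_experts = max(config.n_shared_experts + config.n_unique_experts, 1)
        for i in range(self.n_experts):
            par(f"exp{i}_W1", dense_init(rng, in_dim, config.expert_hidden))
            par(f"exp{i}_b1", np.zeros(config.expert_hidden))
            par(f"exp{i}_W2", dense_init(rng, config.expert_hidden, config.expert_dim))
            par(f"exp{i}_b2", np.zeros(config.expert_dim))
        for t, vt in enumerate(sizes["task_vocab_sizes"]):
            par(f"gate{t}_W", dense_init(rng, in_dim, self.n_experts))
            par(f"gate{t}_b", np.zeros(self.n_experts))
            par(f"tower{t}_W", dense_init(rng, config.expert_dim, config.tower_hidden))
            par(f"tower{t}_b", np.zeros(config.tower_hidden))
            par(f"head{t}_W", dense_init(rng, config.tower_hidden, vt)
                * config.head_init_scale)
            par(f"head{t}_b", np.zeros(vt))
            if config.wide_path:
                par(f"wide{t}_a", np.ones(1))
        self._params = P

    params = MLPNet.params
    zero_grad = MLPNet.zero_grad
    _encode = MLPNet._encode

    def forward(self, batch: dict) -> list[Tensor]:
        P = self._params
        x = self._encode(batch)
        experts = []
        for i in range(self.n_experts):
            hdn = (x @ P[f"exp{i}_W1"] + P[f"exp{i}_b1"]).relu()
            experts.append((hdn @ P[f"exp{i}_W2"] + P[f"exp{i}_b2"]).relu())
        out = []
        for t in range(self.config.n_tasks):
            gate = (x @ P[f"gate{t}_W"] + P[f"gate{t}_b"]).softmax(axis=1)
            gated = None
            for i, E in enumerate(experts):
                term = gate[:, i:i + 1] * E
                gated = term if gated is None else gated + term
            hdn = (gated @ P[f"tower{t}_W"] + P[f"tower{t}_b"]).relu()
            out.append(_wide_term(P, self.config, t,
                                  hdn @ P[f"head{t}_W"] + P[f"head{t}_b"], batch))
        return out


MODEL_KINDS = {"meta": MetaAttentionNet, "mlp": MLPNet, "mmoe": MMoENet}


def build_baseline(kind: str, config: ModelConfig, sizes: dict):
    """Baseline factory sharing the main model's input pipeline and shapes."""
    if kind not in ("mlp", "mmoe"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    return MODEL_KINDS[kind](config, sizes)


def build_model(kind: str, config: ModelConfig, sizes: dict):
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    return MODEL_KINDS[kind](config, sizes)


# -- score merging --------------------------------------------------------

def merge_task_scores(task_scores: list[np.ndarray], task_element_ids: list[list[int]],
                      merge: str = "softmax") -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-task score vectors into one global candidate list.

    ``merge="softmax"`` normalises each task's scores to a distribution
    first (the default global-ranking rule); ``"sigmoid"`` uses the
    per-element probabilities unchanged.  Returns (scores (B, V_all),
    element_ids (V_all,)) in concatenated task order.
    """
    cols = []
    for arr in task_scores:
        if merge == "softmax":
            z = arr - arr.max(axis=1, keepdims=True)
            e = np.exp(z)
            cols.append(e / e.sum(axis=1, keepdims=True))
        elif merge == "sigmoid":
            cols.append(1.0 / (1.0 + np.exp(-arr)))
        else:
            raise ValueError(f"unknown merge {merge!r}")
    ids = np.concatenate([np.asarray(ix, dtype=int) for ix in task_element_ids])
    return np.concatenate(cols, axis=1), ids


# -- checkpointing --------------------------------------------------------

CHECKPOINT_SCHEMA = "tcmrec-checkpoint/1"


def save_checkpoint(model, path: str | Path) -> None:
    """Weights as .npz next to a JSON manifest (schema-versioned)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **{k: v.data for k, v in model.params().items()})
    cfg = asdict(model.config)
    cfg["mlp_hidden"] = list(cfg["mlp_hidden"])
    manifest = {"schema_version": CHECKPOINT_SCHEMA, "kind": model.kind,
                "config": cfg, "sizes": model.sizes}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path):
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("schema_version") != CHECKPOINT_SCHEMA:
        raise ValueError(f"checkpoint schema {manifest.get('schema_version')!r} "
                         f"!= {CHECKPOINT_SCHEMA!r}")
    cfg_dict = dict(manifest["config"])
    cfg_dict["mlp_hidden"] = tuple(cfg_dict["mlp_hidden"])
    config = ModelConfig(**cfg_dict)
    model = build_model(manifest["kind"], config, manifest["sizes"])
    with np.load(path / "weights.npz") as npz:
        for k, p in model.params().items():
            p.data[:] = npz[k]
    return model
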