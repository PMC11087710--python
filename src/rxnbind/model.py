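"""Masked-language-model training harness over joint reaction sequences.

A small bidirectional transformer encoder, implemented directly in numpy
with analytic gradients (verified against finite differences in the test
suite).  The contract is deliberately minimal: token ids in, per-layer
per-head row-stochastic attention matrices out.  Training mixes an
enzymatic corpus (default weight 0.9) with an organic one (default 0.1) by
per-example sampling, applies single-token MLM to the SMILES regions and
n-gram MLM to the enzyme region, and optimizes masked-token cross-entropy
with Adam.

The default desk-scale configuration (2 layers, 4 heads, width 64, a few
thousand steps) trains in minutes on one CPU; larger configurations are a
matter of the same config object.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .tokenization import (
    DEFAULT_MASK_POLICY,
    MASK_ID,
    PAD_ID,
    SPECIAL_TOKENS,
    TokenizedReaction,
    plan_mlm_mask,
    plan_ngram_mask,
)

__all__ = [
    "ModelConfig",
    "MaskingConfig",
    "OptimizerSettings",
    "MixtureSpec",
    "AttentionTensor",
    "TrainedModel",
    "TrainingDivergedError",
    "sample_batch",
    "train_model",
    "masked_loss",
    "attention_forward",
    "save_model",
    "load_model",
]

_IGNORE = -100  # label value for unmasked positions


@dataclass(frozen=True)
class ModelConfig:
    """Encoder shape; ``hidden_dim`` must be divisible by ``heads``."""

    vocab_size: int
    layers: int = 2
    heads: int = 4
    hidden_dim: int = 64
    ffn_dim: int | None = None
    max_positions: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")

    @property
    def ffn(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim


@dataclass(frozen=True)
class MaskingConfig:
    """Sparse MLM on SMILES regions, dense n-gram MLM on the enzyme.

    ``smiles_rate`` follows the standard 15% convention; ``enzyme_rate``
    (the "dense" rate) defaults to 0.30 with span lengths uniform in
    ``ngram_range``.  ``policy`` is the mask/random/keep replacement split.
    """

    smiles_rate: float = 0.15
    enzyme_rate: float = 0.30
    ngram_range: tuple[int, int] = (2, 5)
    policy: tuple[float, float, float] = DEFAULT_MASK_POLICY


@dataclass(frozen=True)
class OptimizerSettings:
    """Adam hyper-parameters."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class MixtureSpec:
    """Enzymatic + organic corpora with per-example sampling weights."""

    enzymatic: list[TokenizedReaction]
    organic: list[TokenizedReaction] = field(default_factory=list)
    enzymatic_weight: float = 0.9
    organic_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.enzymatic_weight < 0 or self.organic_weight < 0:
            raise ValueError("mixture weights must be non-negative")
        if abs(self.enzymatic_weight + self.organic_weight - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.enzymatic_weight > 0 and not self.enzymatic:
            raise ValueError("enzymatic weight > 0 but corpus is empty")
        if self.organic_weight > 0 and not self.organic:
            raise ValueError("organic weight > 0 but corpus is empty")


def sample_batch(
    mix: MixtureSpec, batch_size: int, rng: np.random.Generator
) -> list[TokenizedReaction]:
    """Draw a batch, each example independently enzymatic w.p. its weight."""
    batch = []
    for _ in range(batch_size):
        if rng.random() < mix.enzymatic_weight:
            pool = mix.enzymatic
        else:
            pool = mix.organic
        batch.append(pool[int(rng.integers(len(pool)))])
    return batch


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# --------------------------------------------------------------------------
# Parameters and forward/backward passes
# --------------------------------------------------------------------------


def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    d, f, v = cfg.hidden_dim, cfg.ffn, cfg.vocab_size

    def w(*shape):
        return rng.normal(0.0, 0.02, size=shape)

    params: dict[str, np.ndarray] = {
        "tok_emb": w(v, d),
        "pos_emb": w(cfg.max_positions, d),
        "lnf_g": np.ones(d),
        "lnf_b": np.zeros(d),
        "w_out": w(d, v),
        "b_out": np.zeros(v),
    }
    for i in range(cfg.layers):
        params.update(
            {
                f"l{i}.ln1_g": np.ones(d),
                f"l{i}.ln1_b": np.zeros(d),
                f"l{i}.wq": w(d, d),
                f"l{i}.bq": np.zeros(d),
                f"l{i}.wk": w(d, d),
                f"l{i}.bk": np.zeros(d),
                f"l{i}.wv": w(d, d),
                f"l{i}.bv": np.zeros(d),
                f"l{i}.wo": w(d, d),
                f"l{i}.bo": np.zeros(d),
                f"l{i}.ln2_g": np.ones(d),
                f"l{i}.ln2_b": np.zeros(d),
                f"l{i}.w1": w(d, f),
                f"l{i}.b1": np.zeros(f),
                f"l{i}.w2": w(f, d),
                f"l{i}.b2": np.zeros(d),
            }
        )
    return params


_LN_EPS = 1e-5
_GELU_K = math.sqrt(2.0 / math.pi)


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _ln_bwd(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _gelu_fwd(x):
    t = np.tanh(_GELU_K * (x + 0.044715 * x**3))
    return 0.5 * x * (1.0 + t), t


def _gelu_bwd(dy, x, t):
    du = _GELU_K * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du)


def _linear_bwd(dy, x, w):
    # y = x @ w + b with x (B,T,din)
    din, dout = w.shape
    x2, dy2 = x.reshape(-1, din), dy.reshape(-1, dout)
    return dy @ w.T, x2.T @ dy2, dy2.sum(0)


def _forward(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    ids: np.ndarray,
    valid: np.ndarray,
    need_cache: bool = False,
):
    """Forward pass; returns (logits, attentions, cache).

    ``ids`` and ``valid`` are (B, T); attention keys at invalid (padding)
    positions are suppressed before the softmax, so every attention row is
    a distribution over real tokens.
    """
    B, T = ids.shape
    if T > cfg.max_positions:
        raise ValueError(f"sequence length {T} exceeds max_positions {cfg.max_positions}")
    d, H = cfg.hidden_dim, cfg.heads
    dk = d // H
    scale = 1.0 / math.sqrt(dk)
    key_bias = np.where(valid[:, None, None, :], 0.0, -1e9)

    x = params["tok_emb"][ids] + params["pos_emb"][:T]
    attns: list[np.ndarray] = []
    layer_caches = []
    for i in range(cfg.layers):
        p = lambda name: params[f"l{i}.{name}"]
        a_in, ln1c = _ln_fwd(x, p("ln1_g"), p("ln1_b"))
        q = (a_in @ p("wq") + p("bq")).reshape(B, T, H, dk).transpose(0, 2, 1, 3)
        k = (a_in @ p("wk") + p("bk")).reshape(B, T, H, dk).transpose(0, 2, 1, 3)
        v = (a_in @ p("wv") + p("bv")).reshape(B, T, H, dk).transpose(0, 2, 1, 3)
        s = q @ k.transpose(0, 1, 3, 2) * scale + key_bias
        s -= s.max(-1, keepdims=True)
        e = np.exp(s)
        a = e / e.sum(-1, keepdims=True)
        z = (a @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        attn_out = z @ p("wo") + p("bo")
        x1 = x + attn_out
        f_in, ln2c = _ln_fwd(x1, p("ln2_g"), p("ln2_b"))
        h = f_in @ p("w1") + p("b1")
        ha, t = _gelu_fwd(h)
        f_out = ha @ p("w2") + p("b2")
        x2 = x1 + f_out
        attns.append(a)
        if need_cache:
            layer_caches.append((x, a_in, ln1c, q, k, v, a, z, x1, f_in, ln2c, h, ha, t))
        x = x2
    xf, lnfc = _ln_fwd(x, params["lnf_g"], params["lnf_b"])
    logits = xf @ params["w_out"] + params["b_out"]
    cache = (layer_caches, xf, lnfc, ids, valid) if need_cache else None
    return logits, attns, cache


def _loss_from_logits(logits: np.ndarray, labels: np.ndarray):
    mask = labels != _IGNORE
    n = int(mask.sum())
    if n == 0:
        return 0.0, np.zeros_like(logits), 0
    lm = logits[mask]
    lm = lm - lm.max(-1, keepdims=True)
    lse = np.log(np.exp(lm).sum(-1, keepdims=True))
    logp = lm - lse
    tgt = labels[mask]
    loss = -logp[np.arange(n), tgt].mean()
    dl = np.exp(logp)
    dl[np.arange(n), tgt] -= 1.0
    dlogits = np.zeros_like(logits)
    dlogits[mask] = dl / n
    return float(loss), dlogits, n


def _loss_and_grads(params, cfg: ModelConfig, ids, labels, valid):
    B, T = ids.shape
    d, H = cfg.hidden_dim, cfg.heads
    dk = d // H
    scale = 1.0 / math.sqrt(dk)
    logits, _, cache = _forward(params, cfg, ids, valid, need_cache=True)
    loss, dlogits, n = _loss_from_logits(logits, labels)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    if n == 0:
        return loss, grads, n
    layer_caches, xf, lnfc, _, _ = cache

    dxf, grads["w_out"], grads["b_out"] = _linear_bwd(dlogits, xf, params["w_out"])
    dx, grads["lnf_g"], grads["lnf_b"] = _ln_bwd(dxf, params["lnf_g"], lnfc)

    for i in reversed(range(cfg.layers)):
        p = lambda name: params[f"l{i}.{name}"]
        x, a_in, ln1c, q, k, v, a, z, x1, f_in, ln2c, h, ha, t = layer_caches[i]
        # x2 = x1 + f_out
        df_out = dx
        dha, grads[f"l{i}.w2"], grads[f"l{i}.b2"] = _linear_bwd(df_out, ha, p("w2"))
        dh = _gelu_bwd(dha, h, t)
        df_in, grads[f"l{i}.w1"], grads[f"l{i}.b1"] = _linear_bwd(dh, f_in, p("w1"))
        dln2, grads[f"l{i}.ln2_g"], grads[f"l{i}.ln2_b"] = _ln_bwd(df_in, p("ln2_g"), ln2c)
        dx1 = dx + dln2
        # x1 = x + attn_out
        dattn_out = dx1
        dz, grads[f"l{i}.wo"], grads[f"l{i}.bo"] = _linear_bwd(dattn_out, z, p("wo"))
        dz = dz.reshape(B, T, H, dk).transpose(0, 2, 1, 3)
        da = dz @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dz
        ds = a * (da - (da * a).sum(-1, keepdims=True))
        dq = ds @ k * scale
        dk_ = ds.transpose(0, 1, 3, 2) @ q * scale
        dq = dq.transpose(0, 2, 1, 3).reshape(B, T, d)
        dk_ = dk_.transpose(0, 2, 1, 3).reshape(B, T, d)
        dv = dv.transpose(0, 2, 1, 3).reshape(B, T, d)
        da_in = np.zeros_like(a_in)
        for dproj, wname, bname in ((dq, "wq", "bq"), (dk_, "wk", "bk"), (dv, "wv", "bv")):
            dpart, grads[f"l{i}.{wname}"], grads[f"l{i}.{bname}"] = _linear_bwd(
                dproj, a_in, p(wname)
            )
            da_in += dpart
        dln1, grads[f"l{i}.ln1_g"], grads[f"l{i}.ln1_b"] = _ln_bwd(da_in, p("ln1_g"), ln1c)
        dx = dx1 + dln1

    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][:T] = dx.sum(0)
    return loss, grads, n


# --------------------------------------------------------------------------
# Masking application and batch assembly
# --------------------------------------------------------------------------


def _mask_example(
    enc: TokenizedReaction,
    masking: MaskingConfig,
    rng: np.random.Generator,
    vocab_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (input ids, labels) for one example.

    Reactant and product regions get single-token MLM; the enzyme region
    gets n-gram MLM.  Special tokens are never masked (plans are built over
    content positions only).
    """
    seeds = rng.integers(0, 2**31 - 1, size=3)
    plans = [
        plan_mlm_mask(enc.reactant_positions, masking.smiles_rate, int(seeds[0]), masking.policy),
        plan_mlm_mask(enc.product_positions, masking.smiles_rate, int(seeds[1]), masking.policy),
    ]
    if enc.m_enz:
        plans.append(
            plan_ngram_mask(
                enc.enzyme_positions,
                masking.enzyme_rate,
                masking.ngram_range,
                int(seeds[2]),
                masking.policy,
            )
        )
    inputs = np.array(enc.tokens, dtype=np.int64)
    labels = np.full(len(enc.tokens), _IGNORE, dtype=np.int64)
    n_special = len(SPECIAL_TOKENS)
    for plan in plans:
        for pos, pol in zip(plan.positions, plan.policies):
            labels[pos] = enc.tokens[pos]
            if pol == "mask":
                inputs[pos] = MASK_ID
            elif pol == "random":
                inputs[pos] = int(rng.integers(n_special, vocab_size))
    return inputs, labels


def _assemble_batch(pairs: Sequence[tuple[np.ndarray, np.ndarray]]):
    T = max(len(inp) for inp, _ in pairs)
    B = len(pairs)
    ids = np.full((B, T), PAD_ID, dtype=np.int64)
    labels = np.full((B, T), _IGNORE, dtype=np.int64)
    valid = np.zeros((B, T), dtype=bool)
    for b, (inp, lab) in enumerate(pairs):
        ids[b, : len(inp)] = inp
        labels[b, : len(lab)] = lab
        valid[b, : len(inp)] = True
    return ids, labels, valid


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict[str, np.ndarray]
    loss_log: list[tuple[int, str, float]] = field(default_factory=list)


def train_model(
    mix: MixtureSpec,
    config: ModelConfig,
    masking: MaskingConfig | None = None,
    steps: int = 2000,
    optimizer: OptimizerSettings | None = None,
    batch_size: int = 16,
    seed: int = 0,
    log_every: int = 50,
) -> TrainedModel:
    """Train the encoder with MLM on the corpus mixture.

    Fully deterministic given ``config.seed`` (initialization) and ``seed``
    (batch sampling and masking).  Raises :class:`TrainingDivergedError` if
    the loss becomes non-finite.
    """
    masking = masking or MaskingConfig()
    opt = optimizer or OptimizerSettings()
    params = _init_params(config)
    model = TrainedModel(config, params)
    if steps == 0:
        return model
    rng = np.random.default_rng(seed)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    for step in range(1, steps + 1):
        batch = sample_batch(mix, batch_size, rng)
        pairs = [_mask_example(e, masking, rng, config.vocab_size) for e in batch]
        ids, labels, valid = _assemble_batch(pairs)
        loss, grads, n = _loss_and_grads(params, config, ids, labels, valid)
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite loss at step {step}: {loss}")
        if n == 0:
            continue
        b1c = 1.0 - opt.beta1**step
        b2c = 1.0 - opt.beta2**step
        for key, g in grads.items():
            m_state[key] = opt.beta1 * m_state[key] + (1 - opt.beta1) * g
            v_state[key] = opt.beta2 * v_state[key] + (1 - opt.beta2) * g * g
            params[key] -= (
                opt.learning_rate
                * (m_state[key] / b1c)
                / (np.sqrt(v_state[key] / b2c) + opt.eps)
            )
        if step == 1 or step % log_every == 0 or step == steps:
            model.loss_log.append((step, "mlm", loss))
    return model


def masked_loss(
    model: TrainedModel,
    examples: Sequence[TokenizedReaction],
    masking: MaskingConfig | None = None,
    seed: int = 0,
    batch_size: int = 16,
) -> float:
    """Deterministic held-out masked-token loss (mean over examples)."""
    masking = masking or MaskingConfig()
    rng = np.random.default_rng(seed)
    pairs = [_mask_example(e, masking, rng, model.config.vocab_size) for e in examples]
    total, count = 0.0, 0
    for start in range(0, len(pairs), batch_size):
        ids, labels, valid = _assemble_batch(pairs[start : start + batch_size])
        logits, _, _ = _forward(model.params, model.config, ids, valid)
        loss, _, n = _loss_from_logits(logits, labels)
        total += loss * n
        count += n
    if count == 0:
        raise ValueError("no maskable positions in the evaluation set")
    return total / count


# --------------------------------------------------------------------------
# Attention extraction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AttentionTensor:
    """Per-layer per-head attention of one forward pass.

    ``values`` has shape (layers, heads, l, l) with l the full token count
    (special tokens included; downstream slicing skips them through the
    layout's ``special_positions``).  Every row is a probability
    distribution over key positions.
    """

    values: np.ndarray
    layout: TokenizedReaction

    def __post_init__(self) -> None:
        if self.values.ndim != 4 or self.values.shape[2] != self.values.shape[3]:
            raise ValueError("attention tensor must be (L, H, l, l)")
        if self.values.shape[2] != len(self.layout.tokens):
            raise ValueError("attention size does not match token layout")
        rows = self.values.sum(-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")


def attention_forward(model: TrainedModel, enc: TokenizedReaction) -> AttentionTensor:
    """Run one reaction through the encoder and collect its attention."""
    ids = np.array([enc.tokens], dtype=np.int64)
    valid = np.ones_like(ids, dtype=bool)
    _, attns, _ = _forward(model.params, model.config, ids, valid)
    values = np.stack([a[0] for a in attns])  # (L, H, l, l)
    return AttentionTensor(values=values, layout=enc)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(model.config)), encoding="utf-8")
    np.savez(out / "params.npz", **model.params)
    with open(out / "training_log.tsv", "w", encoding="utf-8") as fh:
        fh.write("step\ttask\tloss\n")
        for step, task, loss in model.loss_log:
            fh.write(f"{step}\t{task}\t{loss:.6f}\n")


def load_model(model_dir: str | Path) -> TrainedModel:
    d = Path(model_dir)
    cfg_raw = json.loads((d / "config.json").read_text(encoding="utf-8"))
    known = ModelConfig.__dataclass_fields__
    config = ModelConfig(**{k: v for k, v in cfg_raw.items() if k in known})
    with np.load(d / "params.npz") as data:
        params = {k: data[k] for k in data.files}
    log: list[tuple[int, str, float]] = []
    log_path = d / "training_log.tsv"
    if log_path.exists():
        for line in log_path.read_text(encoding="utf-8").splitlines()[1:]:
            step, task, loss = line.split("\t")
            log.append((int(step), task, float(loss)))
    return TrainedModel(config, params, log)
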