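"""Encoder-decoder transformer (pre-layer-norm) over token ids.

Two forward paths share one parameter set: a differentiable path built on
the autodiff engine (training) and a plain-NumPy path with key/value caching
(generation).  A consistency test asserts both produce identical logits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .vocab import Vocabulary

NEG_INF = -1e9
DTYPE = np.float32  # training is CPU-bound; single precision is ample


@dataclass
class ModelConfig:
    """Architecture and schedule knobs.

    ``lr_scale`` is the multiplier of the Noam warmup/decay schedule
    (lr = lr_scale * d_model^-0.5 * min(step^-0.5, step * warmup^-1.5)),
    the convention under which "learning rate 1" is a sensible default.
    """

    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 4
    d_ff: int = 256
    dropout: float = 0.1
    batch_size: int = 128
    epochs: int = 30
    nucleus_p: float = 0.9
    lr_scale: float = 1.0
    warmup_steps: int = 400
    max_len: int = 96
    val_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.nucleus_p <= 1.0:
            raise ValueError("nucleus_p must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class ModelState:
    """Parameters + vocabulary + position in training; checkpointable."""

    params: dict[str, np.ndarray]
    vocab: Vocabulary
    config: ModelConfig
    epoch: int = 0
    phase: str = "pretrain"  # or "finetune"

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()},
                          self.vocab, replace(self.config), self.epoch, self.phase)

    def save(self, path) -> None:
        meta = json.dumps({
            "vocab": self.vocab.itos,
            "config": asdict(self.config),
            "epoch": self.epoch,
            "phase": self.phase,
        })
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                     **self.params)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {k: npz[k] for k in npz.files if k != "__meta__"}
        vocab = Vocabulary(meta["vocab"][4:])
        return cls(params, vocab, ModelConfig(**meta["config"]),
                   meta["epoch"], meta["phase"])


def positional_encoding(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model), dtype=DTYPE)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _xavier(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)


def init_params(config: ModelConfig, vocab_size: int, seed: int | None = None) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d, f = config.d_model, config.d_ff
    p: dict[str, np.ndarray] = {
        "embed": rng.normal(0.0, d ** -0.5, size=(vocab_size, d)).astype(DTYPE),
        "out_W": _xavier(rng, d, vocab_size),
        "out_b": np.zeros(vocab_size, dtype=DTYPE),
    }

    def block(prefix: str, cross: bool) -> None:
        for name in ("q", "k", "v", "o"):
            p[f"{prefix}.self_W{name}"] = _xavier(rng, d, d)
        if cross:
            for name in ("q", "k", "v", "o"):
                p[f"{prefix}.cross_W{name}"] = _xavier(rng, d, d)
        p[f"{prefix}.ff_W1"] = _xavier(rng, d, f)
        p[f"{prefix}.ff_b1"] = np.zeros(f, dtype=DTYPE)
        p[f"{prefix}.ff_W2"] = _xavier(rng, f, d)
        p[f"{prefix}.ff_b2"] = np.zeros(d, dtype=DTYPE)
        n_ln = 3 if cross else 2
        for i in range(1, n_ln + 1):
            p[f"{prefix}.ln{i}_g"] = np.ones(d, dtype=DTYPE)
            p[f"{prefix}.ln{i}_b"] = np.zeros(d, dtype=DTYPE)

    for layer in range(config.n_layers):
        block(f"enc{layer}", cross=False)
        block(f"dec{layer}", cross=True)
    for side in ("enc", "dec"):
        p[f"{side}_final_ln_g"] = np.ones(d, dtype=DTYPE)
        p[f"{side}_final_ln_b"] = np.zeros(d, dtype=DTYPE)
    return p


# ---------------------------------------------------------------------------
# differentiable forward (training path)


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, l, d = x.shape
    x = ad.reshape(x, (b, l, n_heads, d // n_heads))
    return ad.transpose(x, (0, 2, 1, 3))  # (B, H, L, dh)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, l, dh = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 1, 3)), (b, l, h * dh))


def _attention(tp: dict, prefix: str, q_in: Tensor, kv_in: Tensor,
               bias: np.ndarray, config: ModelConfig,
               rng, train: bool) -> Tensor:
    """Multi-head attention; ``bias`` is an additive mask broadcastable to
    (B, 1, Lq, Lk)."""
    h = config.n_heads
    dh = config.d_model // h
    q = _split_heads(ad.matmul(q_in, tp[f"{prefix}Wq"]), h)
    k = _split_heads(ad.matmul(kv_in, tp[f"{prefix}Wk"]), h)
    v = _split_heads(ad.matmul(kv_in, tp[f"{prefix}Wv"]), h)
    scores = ad.add(ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                           DTYPE(dh ** -0.5)),
                    Tensor(bias))
    attn = ad.softmax(scores)
    attn = ad.dropout(attn, config.dropout, rng, train)
    out = _merge_heads(ad.matmul(attn, v))
    return ad.matmul(out, tp[f"{prefix}Wo"])


def _ffn(tp: dict, prefix: str, x: Tensor, config: ModelConfig, rng, train: bool) -> Tensor:
    h = ad.relu(ad.add(ad.matmul(x, tp[f"{prefix}ff_W1"]), tp[f"{prefix}ff_b1"]))
    h = ad.dropout(h, config.dropout, rng, train)
    return ad.add(ad.matmul(h, tp[f"{prefix}ff_W2"]), tp[f"{prefix}ff_b2"])


def _ln(tp: dict, name: str, x: Tensor) -> Tensor:
    return ad.layer_norm(x, tp[f"{name}_g"], tp[f"{name}_b"])


def forward_logits(tensor_params: dict[str, Tensor], src_ids: np.ndarray,
                   tgt_in_ids: np.ndarray, config: ModelConfig,
                   rng: np.random.Generator | None = None,
                   train: bool = False) -> Tensor:
    """Teacher-forced logits (B, Lt, V) from padded id matrices."""
    tp = tensor_params
    if rng is None:
        rng = np.random.default_rng(0)
    d = config.d_model
    pe = positional_encoding(max(src_ids.shape[1], tgt_in_ids.shape[1]), d)

    src_pad = (src_ids == 0)
    src_bias = np.where(src_pad[:, None, None, :], NEG_INF, 0.0).astype(DTYPE)

    x = ad.mul(ad.embedding(tp["embed"], src_ids), DTYPE(np.sqrt(d)))
    x = ad.add(x, pe[None, : src_ids.shape[1]])
    x = ad.dropout(x, config.dropout, rng, train)
    for layer in range(config.n_layers):
        pre = f"enc{layer}."
        a = _attention(tp, pre + "self_", _ln(tp, pre + "ln1", x),
                       _ln(tp, pre + "ln1", x), src_bias, config, rng, train)
        x = ad.add(x, ad.dropout(a, config.dropout, rng, train))
        f = _ffn(tp, pre, _ln(tp, pre + "ln2", x), config, rng, train)
        x = ad.add(x, ad.dropout(f, config.dropout, rng, train))
    memory = ad.layer_norm(x, tp["enc_final_ln_g"], tp["enc_final_ln_b"])

    lt = tgt_in_ids.shape[1]
    causal = np.triu(np.full((lt, lt), NEG_INF, dtype=DTYPE), k=1)[None, None]
    tgt_pad_bias = np.where((tgt_in_ids == 0)[:, None, None, :], NEG_INF, 0.0)
    self_bias = (causal + tgt_pad_bias).astype(DTYPE)

    y = ad.mul(ad.embedding(tp["embed"], tgt_in_ids), DTYPE(np.sqrt(d)))
    y = ad.add(y, pe[None, :lt])
    y = ad.dropout(y, config.dropout, rng, train)
    for layer in range(config.n_layers):
        pre = f"dec{layer}."
        a = _attention(tp, pre + "self_", _ln(tp, pre + "ln1", y),
                       _ln(tp, pre + "ln1", y), self_bias, config, rng, train)
        y = ad.add(y, ad.dropout(a, config.dropout, rng, train))
        c = _attention(tp, pre + "cross_", _ln(tp, pre + "ln2", y), memory,
                       src_bias, config, rng, train)
        y = ad.add(y, ad.dropout(c, config.dropout, rng, train))
        f = _ffn(tp, pre, _ln(tp, pre + "ln3", y), config, rng, train)
        y = ad.add(y, ad.dropout(f, config.dropout, rng, train))
    y = ad.layer_norm(y, tp["dec_final_ln_g"], tp["dec_final_ln_b"])
    return ad.add(ad.matmul(y, tp["out_W"]), tp["out_b"])


# ---------------------------------------------------------------------------
# plain-NumPy inference path with KV caching


def _np_ln(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(x.var(axis=-1, keepdims=True) + eps)
    return g * (x - mu) * inv + b


def _np_softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _np_heads(x, h):
    b, l, d = x.shape
    return x.reshape(b, l, h, d // h).transpose(0, 2, 1, 3)


def _np_merge(x):
    b, h, l, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)


def encode_source(params: dict, src_ids: np.ndarray, config: ModelConfig):
    """Run the encoder once; returns (memory, src_bias)."""
    p, d, h = params, config.d_model, config.n_heads
    dh = d // h
    pe = positional_encoding(src_ids.shape[1], d)
    src_bias = np.where((src_ids == 0)[:, None, None, :], NEG_INF, 0.0).astype(DTYPE)
    x = p["embed"][src_ids] * DTYPE(np.sqrt(d)) + pe[None]
    for layer in range(config.n_layers):
        pre = f"enc{layer}."
        xn = _np_ln(x, p[pre + "ln1_g"], p[pre + "ln1_b"])
        q = _np_heads(xn @ p[pre + "self_Wq"], h)
        k = _np_heads(xn @ p[pre + "self_Wk"], h)
        v = _np_heads(xn @ p[pre + "self_Wv"], h)
        a = _np_softmax(q @ k.swapaxes(-1, -2) * dh ** -0.5 + src_bias)
        x = x + _np_merge(a @ v) @ p[pre + "self_Wo"]
        xn = _np_ln(x, p[pre + "ln2_g"], p[pre + "ln2_b"])
        x = x + np.maximum(xn @ p[pre + "ff_W1"] + p[pre + "ff_b1"], 0.0) @ p[pre + "ff_W2"] + p[pre + "ff_b2"]
    memory = _np_ln(x, p["enc_final_ln_g"], p["enc_final_ln_b"])
    return memory, src_bias


class DecodeCache:
    """Per-layer cached keys/values for incremental decoding."""

    def __init__(self, params: dict, config: ModelConfig, memory: np.ndarray,
                 src_bias: np.ndarray):
        self.config = config
        self.params = params
        self.t = 0
        h = config.n_heads
        self.self_k = [None] * config.n_layers
        self.self_v = [None] * config.n_layers
        self.cross_k = []
        self.cross_v = []
        self.src_bias = src_bias[:, :, 0:1, :]  # (B,1,1,Ls)
        for layer in range(config.n_layers):
            pre = f"dec{layer}."
            self.cross_k.append(_np_heads(memory @ params[pre + "cross_Wk"], h))
            self.cross_v.append(_np_heads(memory @ params[pre + "cross_Wv"], h))


def decode_step(cache: DecodeCache, token_ids: np.ndarray) -> np.ndarray:
    """Advance generation by one token per sequence; returns logits (B, V)."""
    p, cfg = cache.params, cache.config
    d, h = cfg.d_model, cfg.n_heads
    dh = d // h
    pe = positional_encoding(cache.t + 1, d)
    y = p["embed"][token_ids][:, None, :] * DTYPE(np.sqrt(d)) + pe[cache.t][None, None]
    for layer in range(cfg.n_layers):
        pre = f"dec{layer}."
        yn = _np_ln(y, p[pre + "ln1_g"], p[pre + "ln1_b"])
        q = _np_heads(yn @ p[pre + "self_Wq"], h)
        k_new = _np_heads(yn @ p[pre + "self_Wk"], h)
        v_new = _np_heads(yn @ p[pre + "self_Wv"], h)
        if cache.self_k[layer] is None:
            cache.self_k[layer], cache.self_v[layer] = k_new, v_new
        else:
            cache.self_k[layer] = np.concatenate([cache.self_k[layer], k_new], axis=2)
            cache.self_v[layer] = np.concatenate([cache.self_v[layer], v_new], axis=2)
        a = _np_softmax(q @ cache.self_k[layer].swapaxes(-1, -2) * dh ** -0.5)
        y = y + _np_merge(a @ cache.self_v[layer]) @ p[pre + "self_Wo"]
        yn = _np_ln(y, p[pre + "ln2_g"], p[pre + "ln2_b"])
        qc = _np_heads(yn @ p[pre + "cross_Wq"], h)
        ac = _np_softmax(qc @ cache.cross_k[layer].swapaxes(-1, -2) * dh ** -0.5
                         + cache.src_bias)
        y = y + _np_merge(ac @ cache.cross_v[layer]) @ p[pre + "cross_Wo"]
        yn = _np_ln(y, p[pre + "ln3_g"], p[pre + "ln3_b"])
        y = y + np.maximum(yn @ p[pre + "ff_W1"] + p[pre + "ff_b1"], 0.0) @ p[pre + "ff_W2"] + p[pre + "ff_b2"]
    y = _np_ln(y, p["dec_final_ln_g"], p["dec_final_ln_b"])
    cache.t += 1
    return (y @ p["out_W"] + p["out_b"])[:, 0, :]
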