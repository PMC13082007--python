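"""Graph transformer with clamped-TMRCA relative positional encoding.

Attention between subgraph tokens is modulated by the relative TMRCA
bucket ``psi(i, j)`` through three learned tables ``P_query``, ``P_key``,
``P_value``, each with ``L = cap + 1`` rows of width ``d_z``:

    q_i = W_query x_i,  k_i = W_key x_i,  v_i = W_value x_i
    a^T_ij = q_i . P_query[psi_ij] + k_j . P_key[psi_ij]
    a_ij   = (q_i . k_j + a^T_ij) / sqrt(d_z)
    z_i    = sum_j softmax_j(a_ij) (v_j + P_value[psi_ij])

Only node-to-node relationships are encoded — no edge features.  The
model stacks multi-head TMRCA attention with pre-layer-norm residual
blocks and feed-forward layers; the ancestry class is read from the focal
token's final representation through a linear four-way head.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from arglai.nn.autograd import Tensor, einsum, gather, relu, softmax
from arglai.nn.layers import Dropout, LayerNorm, Linear, Params, init_params
from arglai.subgraph import DEFAULT_CAP, TokenVocabulary

__all__ = [
    "ModelConfig", "AttentionState", "relative_bias", "attention",
    "build_params", "forward_logits", "forward",
    "save_checkpoint", "load_checkpoint",
]

MASK_NEG = -1e9  # additive logit for masked positions


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``L`` is the number of relative-position rows (the psi cap plus one);
    psi buckets index the tables directly.  ``d_model`` must equal
    ``n_heads * d_z``.  The relative tables are shared across heads within
    a layer; ``share_tables`` additionally shares them across layers.
    ``readout`` is "focal" (classify from the focal token) or "mean"
    (masked mean pooling).
    """

    vocab_size: int
    d_model: int = 128
    n_heads: int = 8
    n_layers: int = 4
    d_ff: int = 512
    L: int = DEFAULT_CAP + 1
    n_classes: int = 4
    dropout: float = 0.1
    share_tables: bool = False
    readout: str = "focal"

    @property
    def d_z(self) -> int:
        return self.d_model // self.n_heads

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be a multiple of n_heads")
        if self.readout not in ("focal", "mean"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass
class AttentionState:
    """Intermediate attention quantities (numpy views, for inspection)."""

    scores: np.ndarray    # raw a_ij
    weights: np.ndarray   # normalized a^_ij, rows sum to 1
    outputs: np.ndarray   # z_i


def _check_psi(psi: np.ndarray, L: int) -> np.ndarray:
    psi = np.asarray(psi, dtype=np.int64)
    if psi.min() < 0 or psi.max() >= L:
        raise ValueError(
            f"psi entries must lie in [0, {L - 1}], "
            f"got range [{psi.min()}, {psi.max()}]")
    return psi


def relative_bias(q: Tensor, k: Tensor, psi: np.ndarray,
                  p_query: Tensor, p_key: Tensor) -> Tensor:
    """TMRCA attention bias a^T_ij = q_i.P_query[psi_ij] + k_j.P_key[psi_ij].

    ``q``/``k`` may carry leading batch/head axes (..., N, d_z); ``psi``
    carries the matching (..., N, N) without the head axis.
    """
    psi = _check_psi(psi, p_query.shape[0])
    pq = gather(p_query, psi)     # (..., N, N, d_z)
    pk = gather(p_key, psi)
    if q.ndim == psi.ndim:        # no head axis
        t1 = einsum("...id,...ijd->...ij", q, pq)
        t2 = einsum("...jd,...ijd->...ij", k, pk)
    elif q.ndim == psi.ndim + 1:  # (..., H, N, d_z) vs psi (..., N, N)
        t1 = einsum("...hid,...ijd->...hij", q, pq)
        t2 = einsum("...hjd,...ijd->...hij", k, pk)
    else:
        raise ValueError("q/psi rank mismatch")
    return t1 + t2


def attention(q: Tensor, k: Tensor, v: Tensor, psi: np.ndarray,
              p_query: Tensor, p_key: Tensor, p_value: Tensor,
              mask: np.ndarray | None = None) -> tuple[Tensor, AttentionState]:
    """One TMRCA-modulated attention pass; returns (z, state).

    ``mask`` is True for real tokens (broadcast over the key axis); an
    all-masked row is an error because its softmax is undefined.
    """
    d_z = q.shape[-1]
    bias = relative_bias(q, k, psi, p_query, p_key)
    if q.ndim == psi.ndim + 1:
        dots = einsum("...hid,...hjd->...hij", q, k)
    else:
        dots = einsum("...id,...jd->...ij", q, k)
    scores = (dots + bias) * (1.0 / np.sqrt(d_z))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=-1).all():
            raise ValueError("attention row with every position masked")
        add = np.where(mask, 0.0, MASK_NEG)             # (..., N)
        if q.ndim == psi.ndim + 1:                      # head axis present
            add = add[..., None, None, :]
        else:
            add = add[..., None, :]
        scores = scores + Tensor(add.astype(scores.data.dtype))
    weights = softmax(scores, axis=-1)
    pv = gather(p_value, _check_psi(psi, p_value.shape[0]))
    if q.ndim == psi.ndim + 1:
        z = einsum("...hij,...hjd->...hid", weights, v) + \
            einsum("...hij,...ijd->...hid", weights, pv)
    else:
        z = einsum("...ij,...jd->...id", weights, v) + \
            einsum("...ij,...ijd->...id", weights, pv)
    state = AttentionState(scores=scores.data, weights=weights.data,
                           outputs=z.data)
    return z, state


def _table_name(cfg: ModelConfig, layer: int, which: str) -> str:
    return f"tables.{which}" if cfg.share_tables else f"layer{layer}.{which}"


def build_params(cfg: ModelConfig, rng: np.random.Generator,
                 dtype=np.float64) -> Params:
    """Allocate and initialize all trainable tensors for ``cfg``."""
    shapes: dict[str, tuple[int, ...]] = {"embed": (cfg.vocab_size, cfg.d_model)}
    for l in range(cfg.n_layers):
        shapes.update(LayerNorm.shapes(f"layer{l}.ln1", cfg.d_model))
        shapes.update(LayerNorm.shapes(f"layer{l}.ln2", cfg.d_model))
        for proj in ("wq", "wk", "wv", "wo"):
            shapes.update(Linear.shapes(f"layer{l}.{proj}",
                                        cfg.d_model, cfg.d_model))
        for which in ("p_query", "p_key", "p_value"):
            shapes[_table_name(cfg, l, which)] = (cfg.L, cfg.d_z)
        shapes.update(Linear.shapes(f"layer{l}.ff1", cfg.d_model, cfg.d_ff))
        shapes.update(Linear.shapes(f"layer{l}.ff2", cfg.d_ff, cfg.d_model))
    shapes.update(LayerNorm.shapes("ln_out", cfg.d_model))
    shapes.update(Linear.shapes("head", cfg.d_model, cfg.n_classes))
    params = init_params(shapes, rng, dtype=dtype)
    # small init for relative tables: start near the vanilla transformer
    for name, t in params.items():
        if ".p_" in name or name.startswith("tables."):
            t.data *= 0.1
    return params


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, n, d = x.shape
    return x.reshape(b, n, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dz = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dz)


def forward_logits(params: Params, cfg: ModelConfig, tokens: np.ndarray,
                   psi: np.ndarray, mask: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Batched forward pass to class logits.

    ``tokens`` (B, S) int, ``psi`` (B, S, S) int, ``mask`` (B, S) bool
    (True = real token).  ``rng`` enables dropout (training mode).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.max() >= cfg.vocab_size or tokens.min() < 0:
        raise ValueError("token id outside vocabulary")
    psi = _check_psi(psi, cfg.L)
    if mask is None:
        mask = np.ones(tokens.shape, dtype=bool)
    x = gather(params["embed"], tokens)              # (B, S, d_model)
    for l in range(cfg.n_layers):
        h = LayerNorm.apply(params, f"layer{l}.ln1", x)
        q = _split_heads(Linear.apply(params, f"layer{l}.wq", h), cfg.n_heads)
        k = _split_heads(Linear.apply(params, f"layer{l}.wk", h), cfg.n_heads)
        v = _split_heads(Linear.apply(params, f"layer{l}.wv", h), cfg.n_heads)
        z, _ = attention(q, k, v, psi,
                         params[_table_name(cfg, l, "p_query")],
                         params[_table_name(cfg, l, "p_key")],
                         params[_table_name(cfg, l, "p_value")],
                         mask=mask)
        z = Linear.apply(params, f"layer{l}.wo", _merge_heads(z))
        x = x + Dropout.apply(z, cfg.dropout, rng)
        h = LayerNorm.apply(params, f"layer{l}.ln2", x)
        h = Linear.apply(params, f"layer{l}.ff2",
                         relu(Linear.apply(params, f"layer{l}.ff1", h)))
        x = x + Dropout.apply(h, cfg.dropout, rng)
    x = LayerNorm.apply(params, "ln_out", x)
    if cfg.readout == "focal":
        read = _select_token(x, 0)
    else:
        w = (mask / mask.sum(axis=-1, keepdims=True)).astype(x.data.dtype)
        read = einsum("bs,bsd->bd", Tensor(w), x)
    return Linear.apply(params, "head", read)


def _select_token(x: Tensor, pos: int) -> Tensor:
    out = Tensor(x.data[:, pos, :], _parents=(x,))

    def bw(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            acc[:, pos, :] = g
            x._accumulate(acc)
    out._backward = bw
    return out


def forward(params: Params, cfg: ModelConfig, tokens: np.ndarray,
            psi: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Class probabilities (B, n_classes); rows sum to 1."""
    logits = forward_logits(params, cfg, tokens, psi, mask, rng=None)
    return softmax(logits, axis=-1).data


CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, cfg: ModelConfig, params: Params,
                    vocab: TokenVocabulary,
                    extra: Optional[dict] = None) -> None:
    """Single-file archive: config echo + parameter blobs + vocabulary."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        "vocab": dict(vocab.token_to_id),
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v.data for k, v in params.items()}
    np.savez(path, header=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelConfig, Params,
                                               TokenVocabulary, dict]:
    with np.load(path) as npz:
        header = json.loads(bytes(npz["header"]).decode())
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        params = {
            k[len("param:"):]: Tensor(npz[k], requires_grad=True)
            for k in npz.files if k.startswith("param:")
        }
    cfg = ModelConfig(**header["config"])
    vocab = TokenVocabulary(token_to_id={k: int(v) for k, v
                                         in header["vocab"].items()})
    return cfg, params, vocab, header.get("extra", {})
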