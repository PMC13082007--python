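"""Layers and optimizer shared by the transformer and the MLP baseline."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from arglai.nn.autograd import Tensor, einsum, relu, softmax

__all__ = ["init_params", "Linear", "LayerNorm", "Dropout", "CrossEntropy",
           "Adam", "Params"]

Params = dict  # name -> Tensor; flat, so checkpoints are a plain npz


def init_params(shapes: Mapping[str, tuple[int, ...]],
                rng: np.random.Generator,
                dtype=np.float64) -> Params:
    """Create trainable tensors; matrices get Xavier-uniform init, vectors
    named ``*.bias``/``*.shift`` get zeros and ``*.gain`` ones."""
    out: Params = {}
    for name, shape in shapes.items():
        if name.endswith(".gain"):
            data = np.ones(shape)
        elif name.endswith((".bias", ".shift")):
            data = np.zeros(shape)
        else:
            fan_in = shape[0] if len(shape) > 1 else shape[-1]
            fan_out = shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            data = rng.uniform(-lim, lim, size=shape)
        out[name] = Tensor(np.asarray(data, dtype=dtype), requires_grad=True)
    return out


class Linear:
    """y = x W + b over the last axis (W stored input-major)."""

    @staticmethod
    def shapes(name: str, d_in: int, d_out: int) -> dict:
        return {f"{name}.weight": (d_in, d_out), f"{name}.bias": (d_out,)}

    @staticmethod
    def apply(params: Params, name: str, x: Tensor) -> Tensor:
        w, b = params[f"{name}.weight"], params[f"{name}.bias"]
        sub_in = "...i,ij->...j"
        return einsum(sub_in, x, w) + b


class LayerNorm:
    """Normalize the last axis to zero mean / unit variance, then affine."""

    EPS = 1e-5

    @staticmethod
    def shapes(name: str, d: int) -> dict:
        return {f"{name}.gain": (d,), f"{name}.shift": (d,)}

    @staticmethod
    def apply(params: Params, name: str, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + LayerNorm.EPS) ** -0.5
        return xc * inv * params[f"{name}.gain"] + params[f"{name}.shift"]


class Dropout:
    """Inverted dropout; identity when rate is 0 or rng is None (eval)."""

    @staticmethod
    def apply(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
        if rng is None or rate <= 0.0:
            return x
        keep = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(
            x.data.dtype)
        return x * Tensor(keep)


class CrossEntropy:
    """Mean negative log-likelihood of integer labels under logits."""

    @staticmethod
    def apply(logits: Tensor, labels: np.ndarray) -> Tensor:
        p = softmax(logits, axis=-1)
        n = logits.shape[0]
        picked = _select_rows(p, np.asarray(labels, dtype=np.int64))
        return -(picked.log().mean())


def _select_rows(p: Tensor, labels: np.ndarray) -> Tensor:
    n = p.shape[0]
    out = Tensor(p.data[np.arange(n), labels], _parents=(p,))

    def bw(g):
        if p.requires_grad:
            acc = np.zeros_like(p.data)
            acc[np.arange(n), labels] = g
            p._accumulate(acc)
    out._backward = bw
    return out


class Adam:
    """Adam with optional cosine learning-rate decay."""

    def __init__(self, params: Params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, total_steps: int | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.total_steps = total_steps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
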