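"""Minimal CPU neural-network engine (numpy, manual backprop).

Implements exactly the pieces the fusion classifiers need: 2-D convolution
(im2col), ReLU, dense layers, layer normalization, 2x2 max pooling, global
average pooling, identity-shortcut residual blocks, softmax cross-entropy
and Adam. Layers cache their forward inputs; ``backward`` accumulates into
``Param.grad`` (call :func:`zero_grad` per step) so weight-shared twins —
created with ``share()``, which copies a layer but keeps the same ``Param``
objects — sum their gradients naturally.

All randomness flows through an explicit ``numpy.random.Generator``; with a
fixed seed and single-threaded BLAS the whole train loop is deterministic.
"""

from __future__ import annotations

import copy
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "LayerNorm",
    "Conv2d",
    "MaxPool2",
    "GlobalAvgPool",
    "Flatten",
    "Sequential",
    "Residual",
    "FusionModel",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "zero_grad",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def zero_grad(params: Iterable[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def share(self) -> "Layer":
        """A twin layer sharing this layer's Params but with its own caches."""
        return copy.copy(self)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class LayerNorm(Layer):
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        n = xhat.shape[-1]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        dxhat = g * self.gamma.value
        return (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        ) / (n * std)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
    ):
        fan_in = in_ch * kernel * kernel
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        )
        self.b = Param(np.zeros(out_ch))
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(
                x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad))
            )
        cols, ho, wo = _im2col(x, self.kernel, self.stride)
        self._cols, self._xshape, self._ho, self._wo = cols, x.shape, ho, wo
        out_ch = self.W.value.shape[0]
        wm = self.W.value.reshape(out_ch, -1)
        out = cols @ wm.T + self.b.value  # (B, L, out)
        return out.transpose(0, 2, 1).reshape(x.shape[0], out_ch, ho, wo)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, out_ch, ho, wo = g.shape
        k, stride, pad = self.kernel, self.stride, self.pad
        gf = g.reshape(b, out_ch, ho * wo).transpose(0, 2, 1)  # (B, L, out)
        self.W.grad += np.einsum("blo,blc->oc", gf, self._cols).reshape(
            self.W.value.shape
        )
        self.b.grad += g.sum(axis=(0, 2, 3))
        wm = self.W.value.reshape(out_ch, -1)
        dcols = (gf @ wm).reshape(b, ho, wo, -1, k, k)  # (B,Ho,Wo,C,k,k)
        _, c, hp, wp = self._xshape
        dxp = np.zeros(self._xshape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (trailing odd row/column dropped)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        v = x[:, :, : 2 * ho, : 2 * wo].reshape(b, c, ho, 2, wo, 2)
        vw = v.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, 4)
        self._idx = vw.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(vw, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, ho, wo = g.shape
        gw = np.zeros((b, c, ho, wo, 4))
        np.put_along_axis(gw, self._idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(b, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._xshape)
        dx[:, :, : 2 * ho, : 2 * wo] = gw.reshape(b, c, 2 * ho, 2 * wo)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._xshape
        return np.broadcast_to(g[:, :, None, None], self._xshape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._xshape)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def share(self) -> "Sequential":
        return Sequential([layer.share() for layer in self.layers])


class Residual(Layer):
    """Identity shortcut: output ``x + F(x)``; F must preserve shape."""

    def __init__(self, inner: Sequential):
        self.inner = inner

    def params(self) -> list[Param]:
        return self.inner.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.inner.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g + self.inner.backward(g)

    def share(self) -> "Residual":
        return Residual(self.inner.share())


class FusionModel:
    """Multi-branch network: per-modality encoders, feature concatenation,
    and a shared classification head."""

    def __init__(self, branches: dict[str, Sequential], head: Sequential,
                 branch_order: Sequence[str] | None = None):
        self.branches = branches
        self.head = head
        self.branch_order = list(branch_order) if branch_order else sorted(branches)

    def params(self) -> list[Param]:
        seen: list[Param] = []
        ids = set()
        for name in self.branch_order:
            for p in self.branches[name].params():
                if id(p) not in ids:
                    ids.add(id(p))
                    seen.append(p)
        for p in self.head.params():
            if id(p) not in ids:
                ids.add(id(p))
                seen.append(p)
        return seen

    def forward(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        feats = [self.branches[k].forward(inputs[k]) for k in self.branch_order]
        self._sizes = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        offset = 0
        for name, size in zip(self.branch_order, self._sizes):
            self.branches[name].backward(dz[:, offset : offset + size])
            offset += size

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(params) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            p.value[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient wrt logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
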