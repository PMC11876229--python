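"""Minimal NumPy neural-network layer with manual backpropagation.

Deliberately small: NCHW convolutions via im2col, average pooling,
fully connected layers, ReLU, global average pooling, softmax /
logistic cross-entropy losses and Adam. Everything is deterministic
given the generator used at initialization, forward passes cache what
the backward pass needs, and gradients are verified against numerical
differentiation in the test suite.

This is all the capacity the desk-scale encoders in this package need;
it is not a general-purpose autograd system.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2d", "Linear", "ReLU", "AvgPool2d",
    "GlobalAvgPool", "Flatten", "Sequential", "Adam",
    "softmax_cross_entropy", "bce_with_logits", "sigmoid",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style convolution on (N, C, H, W), He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = x.shape
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * ho * wo, c * k * k)
        wm = self.W.value.reshape(self.cout, -1)
        out = cols @ wm.T + self.b.value
        self._cache = (cols, (n, c, hp, wp), (ho, wo))
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout):
        cols, (n, c, hp, wp), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        gmat = gout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.W.grad += (gmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=0)
        dcols = (gmat @ self.W.value.reshape(self.cout, -1))
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, hp, wp))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / din), (dout, din)))
        self.b = Param(np.zeros(dout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gout):
        self.W.grad += gout.T @ self._x
        self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class AvgPool2d(Layer):
    """Non-overlapping average pooling; trailing rows/cols that do not
    fill a window are dropped."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x):
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        self._in_shape = (n, c, h, w)
        xt = x[:, :, :ho * k, :wo * k].reshape(n, c, ho, k, wo, k)
        return xt.mean(axis=(3, 5))

    def backward(self, gout):
        k = self.k
        n, c, h, w = self._in_shape
        ho, wo = h // k, w // k
        dx = np.zeros((n, c, h, w))
        g = np.repeat(np.repeat(gout, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, :ho * k, :wo * k] = g
        return dx


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(gout[:, :, None, None], (n, c, h, w)) / (h * w)


class FeatureNorm(Layer):
    """Per-sample standardization of a (N, D) feature vector.

    Makes the features handed to a classification head invariant to the
    overall scale the encoder's weights drifted to during pretraining —
    the property that keeps encoder transfer between tasks stable
    without batch statistics."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._s = np.sqrt(var + self.eps)
        self._y = (x - mu) / self._s
        return self._y

    def backward(self, gout):
        y, s = self._y, self._s
        gm = gout.mean(axis=1, keepdims=True)
        gym = (gout * y).mean(axis=1, keepdims=True)
        return (gout - gm - y * gym) / s


class Flatten(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    def forward(self, x, keep_activations: bool = False):
        acts = [x] if keep_activations else None
        for lyr in self.layers:
            x = lyr.forward(x)
            if keep_activations:
                acts.append(x)
        if keep_activations:
            self.activations = acts
        return x

    def backward(self, gout, stop_at: int | None = None):
        """Backpropagate; with ``stop_at=i`` return the gradient with
        respect to the *output* of layer ``i`` (propagating only through
        the layers above it)."""
        for idx in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and idx == stop_at:
                return gout
            gout = self.layers[idx].backward(gout)
        return gout

    # -- parameter (de)serialization ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, lyr in enumerate(self.layers):
            for j, p in enumerate(lyr.params()):
                state[f"{i}.{j}"] = p.value.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, lyr in enumerate(self.layers):
            for j, p in enumerate(lyr.params()):
                key = f"{i}.{j}"
                if key not in state:
                    raise ValueError(f"missing parameter {key} in state dict")
                if state[key].shape != p.value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{state[key].shape} vs {p.value.shape}"
                    )
                p.value = np.asarray(state[key], dtype=np.float64).copy()


class Adam:
    """Adam with optional decoupled-style L2 (gradient-added weight decay)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, dloss/dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, grad)."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    # stable log(1 + exp(-|x|)) formulation
    loss = np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - y) / len(y)
    return float(loss), grad
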