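"""Minimal NumPy building blocks for 1-D causal convolutional networks.

Implements exactly what the severity classifier needs — causal 1-D
convolution, batch normalisation, ReLU, max pooling, a dense softmax head,
categorical cross-entropy and the Adam optimiser — with hand-written
backward passes.  Arrays are (batch, length, channels) float32; convolutions
are realised as im2col + GEMM so the heavy lifting stays in BLAS.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: params/grads are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


class CausalConv1D(Layer):
    """1-D convolution, left-padded with zeros so the output at time t
    depends only on inputs at <= t and the length is preserved.

    ``l2`` adds ``l2 * sum(W**2)`` to the loss (kernel only, not bias).
    """

    def __init__(self, c_in: int, c_out: int, width: int, *, l2: float = 0.0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (width * c_in))        # He initialisation
        self.width, self.c_in, self.c_out, self.l2 = width, c_in, c_out, l2
        w = (rng.standard_normal((width, c_in, c_out)) * scale).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    @property
    def kernel(self) -> np.ndarray:
        return self.params[0]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        pad = np.zeros((B, self.width - 1, C), dtype=x.dtype)
        xp = np.concatenate([pad, x], axis=1)
        # shifted-GEMM formulation: out[:, t] = sum_k xp[:, t+k] @ W[k]
        # (W[k] weights the input k-(width-1) steps back; no im2col copy)
        out = np.empty((B, L, self.c_out), dtype=x.dtype)
        np.copyto(out, self.params[1])
        for k in range(self.width):
            out += xp[:, k:k + L, :] @ self.kernel[k]
        if training:
            self._xp = xp
        self._in_shape = (B, L, C)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, _ = self._in_shape
        for k in range(self.width):
            self.grads[0][k] = np.tensordot(
                self._xp[:, k:k + L, :], dout, axes=([0, 1], [0, 1]))
        if self.l2:
            self.grads[0] += 2.0 * self.l2 * self.kernel
        self.grads[1][...] = dout.sum(axis=(0, 1))
        dxp = np.zeros((B, L + self.width - 1, self.c_in), dtype=dout.dtype)
        for k in range(self.width):
            dxp[:, k:k + L, :] += dout @ self.kernel[k].T
        return dxp[:, self.width - 1:, :]

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.kernel.astype(np.float64) ** 2))


class BatchNorm1D(Layer):
    """Batch normalisation over (batch, length) per channel.

    Running statistics follow ``running = momentum * running +
    (1 - momentum) * batch`` and are used in inference mode.
    """

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-2) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        gamma = np.ones(c, dtype=np.float32)
        beta = np.zeros(c, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        gamma, beta = self.params
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._inv_std
            return gamma * self._xhat + beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (gamma * inv).astype(x.dtype)
        shift = (beta - self.running_mean * gamma * inv).astype(x.dtype)
        return x * scale + shift

    def backward(self, dout: np.ndarray) -> np.ndarray:
        gamma = self.params[0]
        n = dout.shape[0] * dout.shape[1]
        self.grads[0][...] = np.sum(dout * self._xhat, axis=(0, 1))
        self.grads[1][...] = np.sum(dout, axis=(0, 1))
        dxhat = dout * gamma
        dx = (self._inv_std / n) * (
            n * dxhat - dxhat.sum(axis=(0, 1))
            - self._xhat * np.sum(dxhat * self._xhat, axis=(0, 1)))
        return dx.astype(dout.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (pool == stride).
    A trailing remainder shorter than the pool is dropped."""

    def __init__(self, pool: int = 2, stride: int = 2) -> None:
        super().__init__()
        if pool != stride:
            raise NotImplementedError("only pool == stride supported")
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.pool
        xr = x[:, :Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        if training:   # argmax cache only needed for backprop
            self._argmax = xr.argmax(axis=2)
            self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        Lo = dout.shape[1]
        dx = np.zeros((B, Lo, self.pool, C), dtype=dout.dtype)
        b, l, c = np.ogrid[:B, :Lo, :C]
        dx[b, l, self._argmax, c] = dout
        dx = dx.reshape(B, Lo * self.pool, C)
        if Lo * self.pool < L:
            dx = np.concatenate(
                [dx, np.zeros((B, L - Lo * self.pool, C), dtype=dout.dtype)],
                axis=1)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        b = np.zeros(n_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy; labels are integer class indices."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean CE)/d(logits) for a softmax head."""
    g = probs.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return (g / len(labels)).astype(np.float32)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Adam:
    """Adam optimiser with bias-corrected first and second moments."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
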