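"""Minimal numpy neural-network layers with explicit backpropagation.

Sequence activations flow *time-major* as float64 arrays shaped
``(length, batch, channels)`` — slicing the length axis then yields
contiguous blocks, so a 1-D convolution decomposes into ``k`` shifted GEMMs
with no im2col copies, which is what makes CPU-only training of the
cyclizability model practical.  Dense/LSTM outputs are ``(batch, features)``.

Each layer caches what its backward pass needs during
``forward(..., training=True)``; ``backward`` consumes the upstream
gradient and fills ``grads`` keyed like ``params``.  These layers exist
because the cyclizability model is the package's core and must run
identically on any CPU-only host; they are not a general framework.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

Array = np.ndarray


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: Dict[str, Array] = {}
        self.grads: Dict[str, Array] = {}

    def forward(self, x: Array, training: bool = False) -> Array:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: Array) -> Array:  # pragma: no cover
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1d(Layer):
    """1-D convolution along the length axis, stride 1, 'same' padding.

    Input/output are time-major ``(L, B, C)``.  The weight tensor is
    ``(k, in_channels, out_channels)``; the convolution is computed as a
    sum of k shifted matrix products over the zero-padded input.

    The stem convolution of the network (a 3x4 kernel spanning the full
    one-hot base axis) is exactly this layer with ``in_channels=4``: the
    2-D kernel is valid across the 4-wide base axis, collapsing it, and
    length-preserving along the position axis.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only (same padding)")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = kernel * in_channels
        self.params = {
            "W": glorot_uniform(rng, fan_in, out_channels,
                                (kernel, in_channels, out_channels)),
            "b": np.zeros(out_channels),
        }

    def forward(self, x: Array, training: bool = False) -> Array:
        L, B, C = x.shape
        k, p = self.kernel, (self.kernel - 1) // 2
        W = self.params["W"]
        xp = np.zeros((L + 2 * p, B, C))
        xp[p : p + L] = x
        flat = xp.reshape((L + 2 * p) * B, C)
        y = np.empty((L * B, self.out_channels))
        y[:] = self.params["b"]
        for i in range(k):
            y += flat[i * B : i * B + L * B] @ W[i]
        if training:
            self._xp_flat = flat
            self._shape = (L, B, C)
        return y.reshape(L, B, self.out_channels)

    def backward(self, dout: Array) -> Array:
        L, B, C = self._shape
        k, p = self.kernel, (self.kernel - 1) // 2
        W = self.params["W"]
        flat = self._xp_flat
        dy = dout.reshape(L * B, self.out_channels)
        dW = np.empty_like(W)
        dxp = np.zeros(((L + 2 * p) * B, C))
        for i in range(k):
            block = flat[i * B : i * B + L * B]
            dW[i] = block.T @ dy
            dxp[i * B : i * B + L * B] += dy @ W[i].T
        self.grads = {"W": dW, "b": dy.sum(axis=0)}
        self._xp_flat = None
        return dxp.reshape(L + 2 * p, B, C)[p : p + L]


class ReLU(Layer):
    def forward(self, x: Array, training: bool = False) -> Array:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: Array) -> Array:
        return dout * self._mask


class MaxPool1d(Layer):
    """Max pooling with window 2 and stride 2 along the (leading) length
    axis of a time-major tensor.

    An odd trailing element is dropped (floor semantics), matching standard
    'valid' pooling length bookkeeping.
    """

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        if pool != 2:
            raise ValueError("pool size 2 only")
        self.pool = pool

    def forward(self, x: Array, training: bool = False) -> Array:
        L = x.shape[0]
        Lp = L // 2
        a, b = x[0 : 2 * Lp : 2], x[1 : 2 * Lp : 2]
        mask = a >= b  # ties take the earlier position
        if training:
            self._mask = mask
            self._in_len = L
        return np.where(mask, a, b)

    def backward(self, dout: Array) -> Array:
        L = self._in_len
        Lp = L // 2
        dx = np.zeros((L,) + dout.shape[1:])
        dx[0 : 2 * Lp : 2] = dout * self._mask
        dx[1 : 2 * Lp : 2] = dout * ~self._mask
        return dx


class BatchNorm(Layer):
    """Batch normalization per channel over all leading axes.

    Evaluation mode uses exponential running moments so that prediction is a
    deterministic function of the input alone.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Array, training: bool = False) -> Array:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv
            self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[-1]
            return self.params["gamma"] * xhat + self.params["beta"]
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * (x - self.running_mean) * inv + self.params["beta"]

    def backward(self, dout: Array) -> Array:
        axes = tuple(range(dout.ndim - 1))
        xhat, inv, n = self._xhat, self._inv, self._n
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        dxhat = dout * g
        dx = (inv / n) * (
            n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._xhat = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: Array, training: bool = False) -> Array:
        if not training or self.rate == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: Array) -> Array:
        if self.rate == 0.0:
            return dout
        return dout * self._mask


class LSTM(Layer):
    """Unidirectional LSTM over a time-major ``(T, B, D)`` input, returning
    the final hidden state ``(B, H)``.

    Gate layout in the packed weight matrices is (input, forget, cell,
    output).  The forget-gate bias is initialized to 1, a standard
    stabilizer for short sequences.
    """

    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.units = units
        self.params = {
            "W": glorot_uniform(rng, in_features, units, (in_features, 4 * units)),
            "U": glorot_uniform(rng, units, units, (units, 4 * units)),
            "b": np.zeros(4 * units),
        }
        self.params["b"][units : 2 * units] = 1.0

    @staticmethod
    def _sigmoid(z: Array) -> Array:
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x: Array, training: bool = False) -> Array:
        T, B, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        xw = x.reshape(T * B, -1) @ W  # hoisted out of the time loop
        xw = xw.reshape(T, B, 4 * H)
        for t in range(T):
            z = xw[t] + h @ U + b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            if training:
                cache.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
        if training:
            self._cache, self._x = cache, x
        return h

    def backward(self, dout: Array) -> Array:
        x, cache = self._x, self._cache
        T, B, D = x.shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dout.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += x[t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[t] = dz @ W.T
            dh = dz @ U.T
            dc = dc * f
        self.grads = {"W": dW, "U": dU, "b": db}
        self._cache = self._x = None
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, in_features, out_features, (in_features, out_features)),
            "b": np.zeros(out_features),
        }

    def forward(self, x: Array, training: bool = False) -> Array:
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: Array) -> Array:
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        dx = dout @ self.params["W"].T
        self._x = None
        return dx
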