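"""The inception-residual + LSTM (IR+LSTM) regression network.

Layer order, mirroring the published architecture diagram:

1. stem: a 3x4 two-dimensional convolution collapsing the one-hot base axis
   (equivalently a kernel-3 1-D convolution over 4 input channels), ReLU,
   batch-norm, dropout — no pooling at the stem;
2. inception module on the stem output, two parallel branches of two serial
   convolutions each: branch 1 uses kernel 3 twice, branch 2 uses kernels 11
   then 21.  Each convolution is followed by ReLU; the *second* convolution
   of each branch additionally gets a 2x1 max-pool before batch-norm and
   dropout (the first convolution of each branch is pool-free);
3. channel-wise concatenation of the branch outputs;
4. residual shortcut: the inception-module input, max-pooled 2x1 so lengths
   agree, added elementwise onto the concatenation;
5. 2x1 max-pool, batch-norm, dropout;
6. LSTM with 20 hidden memory units over the remaining length axis (final
   hidden state read out), dropout;
7. dense layer with linear activation producing one real number.

Stride is 1 throughout and all convolutions are length-preserving.  For a
50-bp input the length bookkeeping is 50 -> 50 (stem) -> 50 (branch convs)
-> 25 (branch pools) -> 25 (residual add) -> 12 (post pool) -> LSTM over 12
steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Tuple

import numpy as np

from .layers import BatchNorm, Conv1d, Dense, Dropout, LSTM, MaxPool1d, ReLU, Layer


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyper-shape of the IR+LSTM network.

    ``filters_per_branch * 2`` must equal ``stem_filters`` so that the
    concatenated branch output is shape-compatible with the residual
    shortcut for elementwise addition.
    """

    input_length: int = 50
    stem_filters: int = 64
    filters_per_branch: int = 32
    branch1_kernels: Tuple[int, int] = (3, 3)
    branch2_kernels: Tuple[int, int] = (11, 21)
    lstm_units: int = 20
    dropout_rate: float = 0.2
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.filters_per_branch * 2 != self.stem_filters:
            raise ValueError(
                "filters_per_branch * 2 must equal stem_filters for the "
                "residual addition to be shape-consistent"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        d = json.loads(text)
        d["branch1_kernels"] = tuple(d["branch1_kernels"])
        d["branch2_kernels"] = tuple(d["branch2_kernels"])
        return cls(**d)


class IRLSTMNetwork:
    """Buildable/evaluable IR+LSTM network mapping (B, L, 4) -> (B,)."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config
        F, Fb, d = c.stem_filters, c.filters_per_branch, c.dropout_rate

        self.stem_conv = Conv1d(4, F, 3, rng)
        self.stem_relu = ReLU()
        self.stem_bn = BatchNorm(F)
        self.stem_drop = Dropout(d)

        self.b1_conv1 = Conv1d(F, Fb, c.branch1_kernels[0], rng)
        self.b1_relu1 = ReLU()
        self.b1_bn1 = BatchNorm(Fb)
        self.b1_drop1 = Dropout(d)
        self.b1_conv2 = Conv1d(Fb, Fb, c.branch1_kernels[1], rng)
        self.b1_relu2 = ReLU()
        self.b1_pool = MaxPool1d(c.pool_size)
        self.b1_bn2 = BatchNorm(Fb)
        self.b1_drop2 = Dropout(d)

        self.b2_conv1 = Conv1d(F, Fb, c.branch2_kernels[0], rng)
        self.b2_relu1 = ReLU()
        self.b2_bn1 = BatchNorm(Fb)
        self.b2_drop1 = Dropout(d)
        self.b2_conv2 = Conv1d(Fb, Fb, c.branch2_kernels[1], rng)
        self.b2_relu2 = ReLU()
        self.b2_pool = MaxPool1d(c.pool_size)
        self.b2_bn2 = BatchNorm(Fb)
        self.b2_drop2 = Dropout(d)

        self.shortcut_pool = MaxPool1d(c.pool_size)
        self.post_pool = MaxPool1d(c.pool_size)
        self.post_bn = BatchNorm(F)
        self.post_drop = Dropout(d)

        self.lstm = LSTM(F, c.lstm_units, rng)
        self.lstm_drop = Dropout(d)
        self.head = Dense(c.lstm_units, 1, rng)

        self._layers: List[Layer] = [
            self.stem_conv, self.stem_relu, self.stem_bn, self.stem_drop,
            self.b1_conv1, self.b1_relu1, self.b1_bn1, self.b1_drop1,
            self.b1_conv2, self.b1_relu2, self.b1_pool, self.b1_bn2, self.b1_drop2,
            self.b2_conv1, self.b2_relu1, self.b2_bn1, self.b2_drop1,
            self.b2_conv2, self.b2_relu2, self.b2_pool, self.b2_bn2, self.b2_drop2,
            self.shortcut_pool, self.post_pool, self.post_bn, self.post_drop,
            self.lstm, self.lstm_drop, self.head,
        ]
        # sanity: the residual add must be shape-consistent
        if 2 * c.filters_per_branch != c.stem_filters:  # pragma: no cover
            raise ValueError("residual shapes inconsistent")

    # -- dropout RNG plumbing -------------------------------------------------
    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self._layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != 4:
            raise ValueError("input must be (batch, length, 4)")
        if x.shape[1] != self.config.input_length:
            raise ValueError(
                f"input length {x.shape[1]} != configured {self.config.input_length}"
            )
        x = np.ascontiguousarray(x.transpose(1, 0, 2))  # time-major (L, B, 4)
        t = training
        s = self.stem_drop.forward(
            self.stem_bn.forward(
                self.stem_relu.forward(self.stem_conv.forward(x, t), t), t), t)

        a = self.b1_drop1.forward(
            self.b1_bn1.forward(
                self.b1_relu1.forward(self.b1_conv1.forward(s, t), t), t), t)
        a = self.b1_drop2.forward(
            self.b1_bn2.forward(
                self.b1_pool.forward(
                    self.b1_relu2.forward(self.b1_conv2.forward(a, t), t), t), t), t)

        b = self.b2_drop1.forward(
            self.b2_bn1.forward(
                self.b2_relu1.forward(self.b2_conv1.forward(s, t), t), t), t)
        b = self.b2_drop2.forward(
            self.b2_bn2.forward(
                self.b2_pool.forward(
                    self.b2_relu2.forward(self.b2_conv2.forward(b, t), t), t), t), t)

        cat = np.concatenate([a, b], axis=2)
        res = cat + self.shortcut_pool.forward(s, t)

        p = self.post_drop.forward(
            self.post_bn.forward(self.post_pool.forward(res, t), t), t)
        h = self.lstm_drop.forward(self.lstm.forward(p, t), t)
        return self.head.forward(h, t)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        Fb = self.config.filters_per_branch
        dh = self.head.backward(dout[:, None])
        dp = self.lstm.backward(self.lstm_drop.backward(dh))
        dres = self.post_pool.backward(
            self.post_bn.backward(self.post_drop.backward(dp)))
        # residual fans out: gradient flows to the concatenation and shortcut
        dcat = dres
        ds = self.shortcut_pool.backward(dres)
        da, db = dcat[:, :, :Fb], dcat[:, :, Fb:]

        da = self.b1_conv2.backward(
            self.b1_relu2.backward(
                self.b1_pool.backward(
                    self.b1_bn2.backward(self.b1_drop2.backward(da)))))
        ds = ds + self.b1_conv1.backward(
            self.b1_relu1.backward(
                self.b1_bn1.backward(self.b1_drop1.backward(da))))

        db = self.b2_conv2.backward(
            self.b2_relu2.backward(
                self.b2_pool.backward(
                    self.b2_bn2.backward(self.b2_drop2.backward(db)))))
        ds = ds + self.b2_conv1.backward(
            self.b2_relu1.backward(
                self.b2_bn1.backward(self.b2_drop1.backward(db))))

        self.stem_conv.backward(
            self.stem_relu.backward(
                self.stem_bn.backward(self.stem_drop.backward(ds))))

    # -- parameter access -----------------------------------------------------
    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """(param, grad) pairs in a stable order, for the optimizer."""
        out = []
        for layer in self._layers:
            for name in sorted(layer.params):
                out.append((layer.params[name], layer.grads[name]))
        return out

    def param_count(self) -> int:
        """Number of trainable parameters (excludes BN running moments)."""
        return sum(layer.param_count() for layer in self._layers)

    def get_weights(self) -> List[np.ndarray]:
        """All state needed to reproduce predictions, in a stable order
        (trainable parameters plus batch-norm running moments)."""
        ws: List[np.ndarray] = []
        for layer in self._layers:
            for name in sorted(layer.params):
                ws.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm):
                ws.append(layer.running_mean.copy())
                ws.append(layer.running_var.copy())
        return ws

    def set_weights(self, weights: List[np.ndarray]) -> None:
        expected = sum(
            len(layer.params) + 2 * isinstance(layer, BatchNorm)
            for layer in self._layers
        )
        if len(weights) != expected:
            raise ValueError(
                f"expected {expected} weight arrays, got {len(weights)}"
            )
        it = iter(weights)
        for layer in self._layers:
            for name in sorted(layer.params):
                w = next(it)
                if w.shape != layer.params[name].shape:
                    raise ValueError("weight shape mismatch during load")
                layer.params[name] = w.copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def zero_weights(self) -> None:
        """Set every trainable parameter to zero (diagnostic use)."""
        for layer in self._layers:
            for name in layer.params:
                layer.params[name] = np.zeros_like(layer.params[name])
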