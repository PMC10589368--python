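"""Neural-network layers built on the :mod:`crisprhw.nn.tensor` autodiff core.

All sequence layers use channels-last layout: (batch, positions, channels).
Weights are Glorot-uniform initialised from a caller-supplied
``numpy.random.Generator`` so model construction is fully reproducible.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .tensor import (
    DTYPE,
    Tensor,
    batchnorm,
    concat,
    conv1d_same,
    embedding_lookup,
    lstm_recurrence,
)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(DTYPE), requires_grad=True)


def zeros(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape, dtype=DTYPE), requires_grad=True)


class Layer:
    """Base class: a named container of trainable parameters."""

    name: str = "layer"

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Embedding(Layer):
    """Token → dense-vector lookup table (vocabulary × embedding_dim)."""

    name = "embedding"

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, 0.05, size=(vocab_size, dim)).astype(DTYPE),
            requires_grad=True,
        )

    def __call__(self, tokens: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, tokens)


class Dense(Layer):
    """Affine map on the last axis, optionally followed by an activation."""

    name = "dense"

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        activation: str | None = None,
    ):
        self.weight = glorot(rng, (n_in, n_out), n_in, n_out)
        self.bias = zeros((n_out,))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight + self.bias
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "tanh":
            out = out.tanh()
        return out


class Conv1D(Layer):
    """Same-padded 1-D convolution over the position axis."""

    name = "conv1d"

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.weight = glorot(
            rng, (kernel, n_in, n_out), kernel * n_in, kernel * n_out
        )
        self.bias = zeros((n_out,))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.weight, self.bias)


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over the batch and position axes.

    Batch statistics are used in training; exponential running statistics
    (momentum 0.9) at inference.  ``set_identity`` pins the layer to the
    identity map, which the residual-block pass-through contract relies on.
    """

    name = "batchnorm"

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Tensor(np.ones((1, 1, channels), dtype=DTYPE), requires_grad=True)
        self.beta = zeros((1, 1, channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, 1, channels), dtype=DTYPE)
        self.running_var = np.ones((1, 1, channels), dtype=DTYPE)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.data.mean(axis=(0, 1), keepdims=True)
            var = x.data.var(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        return batchnorm(x, self.gamma, self.beta, mu, var, self.eps, batch_stats=train)

    def set_identity(self) -> None:
        self.gamma.data[...] = 1.0
        self.beta.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0 - self.eps


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class LSTM(Layer):
    """Single-direction LSTM over the position axis, returning all hidden states."""

    name = "lstm"

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = glorot(rng, (n_in, 4 * hidden), n_in, 4 * hidden)
        self.wh = glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden)
        bias = np.zeros((4 * hidden,), dtype=DTYPE)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        # input contribution to all gates in one matmul; recurrence is fused
        return lstm_recurrence(x @ self.wx + self.bias, self.wh, reverse=reverse)


class BLSTM(Layer):
    """Bidirectional LSTM: forward and reverse passes concatenated per position."""

    name = "blstm"

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.forward = LSTM(n_in, hidden, rng)
        self.backward = LSTM(n_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.forward(x), self.backward(x, reverse=True)], axis=-1)


class SelfAttention(Layer):
    """Single-head scaled dot-product self-attention over the 23 positions.

    Learns which alignment positions to weight most when scoring a pair —
    mid-protospacer bulges and PAM-proximal mismatches matter more than
    PAM-distal ones, and the attention map is free to express that.
    """

    name = "attention"

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.wq = glorot(rng, (dim, dim), dim, dim)
        self.wk = glorot(rng, (dim, dim), dim, dim)
        self.wv = glorot(rng, (dim, dim), dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        q = x @ self.wq
        k = x @ self.wk
        v = x @ self.wv
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.dim))
        return scores.softmax(axis=-1) @ v
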