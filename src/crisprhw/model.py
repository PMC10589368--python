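"""The hybrid parallel off-target network and its ablation variants.

The architecture has four stages:

1. **Sequence encoding** — the 23 integer tokens (one per aligned base pair,
   vocabulary 25) pass through a 90-dimensional embedding.
2. **Feature extraction** — two same-padded 1-D convolutions (kernel 4 → 70
   filters, kernel 6 → 40 filters), each followed by batch normalisation and
   ReLU; the 23-position axis is preserved throughout.
3. **Hybrid parallel layer** — three branches run side by side on the
   extracted features: a modified one-dimensional residual block (two
   kernel-5 convolutions with batch norm and a skip addition), a
   bidirectional LSTM, and single-head scaled dot-product self-attention.
   The attention branch's input is a skip fusion: the embedding output,
   projected to the feature width, added element-wise to the
   feature-extraction output.  Branch outputs are flattened and concatenated.
4. **Dense head** — fully connected 300 → 100 → 2 with ReLU and dropout 0.2
   after the first two layers; the final pair of logits is softmaxed into
   (inactive, active) probabilities.

Ablation variants each omit exactly one named component; the ``serial``
variant keeps all components but chains them (residual block → BLSTM →
attention) instead of running them in parallel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import VOCABULARY_SIZE
from .io_data import PAIR_LENGTH
from .nn import (
    BLSTM,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    SelfAttention,
    Tensor,
    concat,
    no_grad,
)

VARIANTS = ("full", "no_blstm", "no_resnet", "no_attention", "no_dense", "serial")


@dataclass
class ModelSpec:
    """Hyperparameters of the network; defaults are the published configuration."""

    vocabulary_size: int = VOCABULARY_SIZE
    sequence_length: int = PAIR_LENGTH
    embedding_dim: int = 90
    feature_convs: list[tuple[int, int]] = field(
        default_factory=lambda: [(4, 70), (6, 40)]
    )
    residual_kernel: int = 5
    blstm_units: int = 64
    attention_kind: str = "scaled_dot_product"
    dense_units: list[int] = field(default_factory=lambda: [300, 100, 2])
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.dense_units[-1] != 2:
            raise ValueError("dense head must end in 2 output units")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in (0, 1)")
        self.feature_convs = [tuple(kf) for kf in self.feature_convs]

    @property
    def feature_width(self) -> int:
        return self.feature_convs[-1][1]

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(**d)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @staticmethod
    def from_json(path: str | Path) -> "ModelSpec":
        return ModelSpec.from_dict(json.loads(Path(path).read_text()))


class HybridNetwork:
    """A built, trainable off-target classifier for one :class:`ModelSpec` variant."""

    def __init__(self, spec: ModelSpec, variant: str = "full", seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.spec = spec
        self.variant = variant
        rng = np.random.default_rng(seed)
        L = spec.sequence_length
        E = spec.embedding_dim
        W = spec.feature_width

        self.embedding = Embedding(spec.vocabulary_size, E, rng)

        # feature extraction: conv -> BN -> ReLU, twice
        self.convs: list[Conv1D] = []
        self.conv_bns: list[BatchNorm1D] = []
        c_in = E
        for kernel, filters in spec.feature_convs:
            self.convs.append(Conv1D(c_in, filters, kernel, rng))
            self.conv_bns.append(BatchNorm1D(filters))
            c_in = filters

        self.has_resnet = variant != "no_resnet"
        self.has_blstm = variant != "no_blstm"
        self.has_attention = variant != "no_attention"
        self.has_dense = variant != "no_dense"

        if self.has_resnet:
            self.res_conv1 = Conv1D(W, W, spec.residual_kernel, rng)
            self.res_bn1 = BatchNorm1D(W)
            self.res_conv2 = Conv1D(W, W, spec.residual_kernel, rng)
            self.res_bn2 = BatchNorm1D(W)
        if self.has_blstm:
            blstm_in = W
            self.blstm = BLSTM(blstm_in, spec.blstm_units, rng)
        if self.has_attention:
            if variant == "serial":
                attn_dim = 2 * spec.blstm_units if self.has_blstm else W
            else:
                attn_dim = W
                self.attn_proj = Dense(E, W, rng)  # embedding -> feature width
            self.attention = SelfAttention(attn_dim, rng)

        flat = self._flattened_width()
        self._drop_rng = np.random.default_rng(seed + 1)
        if self.has_dense:
            d1, d2, d_out = spec.dense_units
            self.dense1 = Dense(flat, d1, rng, activation="relu")
            self.dropout1 = Dropout(spec.dropout_rate, self._drop_rng)
            self.dense2 = Dense(d1, d2, rng, activation="relu")
            self.dropout2 = Dropout(spec.dropout_rate, self._drop_rng)
            self.dense_out = Dense(d2, d_out, rng)
        else:
            self.dense_out = Dense(flat, 2, rng)

    # -- structure --------------------------------------------------------

    def _flattened_width(self) -> int:
        L, W = self.spec.sequence_length, self.spec.feature_width
        if self.variant == "serial":
            dim = W
            if self.has_blstm:
                dim = 2 * self.spec.blstm_units
            return L * dim
        width = 0
        if self.has_resnet:
            width += L * W
        if self.has_blstm:
            width += L * 2 * self.spec.blstm_units
        if self.has_attention:
            width += L * W
        return width

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = [self.embedding.weight]
        layers = self.convs + self.conv_bns
        if self.has_resnet:
            layers += [self.res_conv1, self.res_bn1, self.res_conv2, self.res_bn2]
        if self.has_blstm:
            layers += [self.blstm]
        if self.has_attention:
            if hasattr(self, "attn_proj"):
                layers += [self.attn_proj]
            layers += [self.attention]
        if self.has_dense:
            layers += [self.dense1, self.dense2, self.dense_out]
        else:
            layers += [self.dense_out]
        for layer in layers:
            params.extend(layer.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def layer_inventory(self) -> dict:
        """Structural description: stages, parallel branches, parameter count."""
        branches: list[str] = []
        if self.variant == "serial":
            branches = []  # single chained path, no parallel branches
        else:
            if self.has_resnet:
                branches.append("residual_block")
            if self.has_blstm:
                branches.append("blstm")
            if self.has_attention:
                branches.append("attention")
        return {
            "variant": self.variant,
            "embedding": (self.spec.vocabulary_size, self.spec.embedding_dim),
            "feature_convs": list(self.spec.feature_convs),
            "parallel_branches": branches,
            "serial_chain": (
                ["residual_block", "blstm", "attention"]
                if self.variant == "serial"
                else None
            ),
            "dense_units": list(self.spec.dense_units) if self.has_dense else [2],
            "n_parameters": self.n_parameters(),
        }

    # -- forward ----------------------------------------------------------

    def _features(self, tokens: np.ndarray, train: bool) -> tuple[Tensor, Tensor]:
        emb = self.embedding(tokens)
        x = emb
        for conv, bn in zip(self.convs, self.conv_bns):
            x = bn(conv(x), train).relu()
        return emb, x

    def _residual(self, x: Tensor, train: bool) -> Tensor:
        y = self.res_bn1(self.res_conv1(x), train).relu()
        y = self.res_bn2(self.res_conv2(y), train)
        return (y + x).relu()

    def forward(self, tokens: np.ndarray, train: bool = False) -> Tensor:
        """Logits (batch, 2) for a batch of token sequences."""
        if tokens.ndim != 2 or tokens.shape[1] != self.spec.sequence_length:
            raise ValueError(f"expected (n, {self.spec.sequence_length}) tokens")
        if tokens.min() < 0 or tokens.max() >= self.spec.vocabulary_size:
            raise ValueError("token outside vocabulary")
        batch = tokens.shape[0]
        emb, feats = self._features(tokens, train)

        if self.variant == "serial":
            x = feats
            if self.has_resnet:
                x = self._residual(x, train)
            if self.has_blstm:
                x = self.blstm(x)
            if self.has_attention:
                x = self.attention(x)
            fused = x.reshape(batch, x.shape[1] * x.shape[2])
        else:
            outputs: list[Tensor] = []
            if self.has_resnet:
                r = self._residual(feats, train)
                outputs.append(r.reshape(batch, r.shape[1] * r.shape[2]))
            if self.has_blstm:
                b = self.blstm(feats)
                outputs.append(b.reshape(batch, b.shape[1] * b.shape[2]))
            if self.has_attention:
                skip = self.attn_proj(emb) + feats
                a = self.attention(skip)
                outputs.append(a.reshape(batch, a.shape[1] * a.shape[2]))
            fused = outputs[0] if len(outputs) == 1 else concat(outputs, axis=-1)

        if self.has_dense:
            x = self.dropout1(self.dense1(fused), train)
            x = self.dropout2(self.dense2(x), train)
            return self.dense_out(x)
        return self.dense_out(fused)

    def predict(self, tokens: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """(inactive, active) softmax probabilities, deterministic in eval mode."""
        probs = []
        with no_grad():
            for start in range(0, len(tokens), batch_size):
                logits = self.forward(tokens[start : start + batch_size], train=False)
                probs.append(logits.softmax(axis=-1).data)
        return np.concatenate(probs, axis=0) if probs else np.empty((0, 2))

    # -- persistence -------------------------------------------------------

    def _batchnorms(self) -> list[BatchNorm1D]:
        bns = list(self.conv_bns)
        if self.has_resnet:
            bns += [self.res_bn1, self.res_bn2]
        return bns

    def save_weights(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        np.savez(path, **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    def load_weights(self, path: str | Path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.parameters()):
                saved = data[f"param_{i}"]
                if saved.shape != p.data.shape:
                    raise ValueError(
                        f"weight {i} shape mismatch: {saved.shape} vs {p.data.shape}"
                    )
                p.data[...] = saved
            for i, bn in enumerate(self._batchnorms()):
                bn.running_mean[...] = data[f"bn_mean_{i}"]
                bn.running_var[...] = data[f"bn_var_{i}"]


def build_model(
    spec: ModelSpec | None = None, variant: str = "full", seed: int = 0
) -> HybridNetwork:
    """Construct a :class:`HybridNetwork`; the default spec is the published one."""
    return HybridNetwork(spec or ModelSpec(), variant=variant, seed=seed)
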