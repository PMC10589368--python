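"""Shared fixtures: tiny model specs and programmatically built datasets."""

from __future__ import annotations

import numpy as np
import pytest

from crisprhw import Dataset, GuideTargetPair, ModelSpec, TrainConfig

BASES = "ACGT"


def random_pair(
    rng: np.random.Generator,
    label: int = 0,
    n_mismatch: int = 0,
    bulge: tuple[int, str] | None = None,
    reads: int | None = None,
) -> GuideTargetPair:
    """Build one valid aligned pair with the requested perturbations."""
    guide = list(rng.choice(list(BASES), size=23))
    target = guide.copy()
    positions = rng.choice(20, size=n_mismatch, replace=False)
    for pos in positions:
        target[pos] = rng.choice([b for b in BASES if b != guide[pos]])
    if bulge is not None:
        pos, kind = bulge
        if kind == "rna":
            guide[pos] = "-"
        else:
            target[pos] = "-"
    return GuideTargetPair("".join(guide), "".join(target), label, reads=reads)


def make_dataset(
    rng: np.random.Generator, n: int, n_pos: int, name: str = "toy"
) -> Dataset:
    pairs = [
        random_pair(rng, label=1 if i < n_pos else 0, n_mismatch=int(rng.integers(0, 4)))
        for i in range(n)
    ]
    return Dataset(name, pairs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def tiny_spec() -> ModelSpec:
    """A shrunken architecture for fast structural/training tests."""
    return ModelSpec(
        embedding_dim=12,
        feature_convs=[(4, 10), (6, 8)],
        blstm_units=6,
        dense_units=[16, 8, 2],
    )


@pytest.fixture
def fast_config() -> TrainConfig:
    return TrainConfig(epochs=2, batch_size=128, shuffle_seed=0)
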