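"""Training protocol and evaluation metrics.

Training follows the published recipe: stratified 5-fold cross-validation
with shuffling, categorical cross-entropy on two-column one-hot targets,
Adam starting at learning rate 0.003, and a reduce-on-plateau schedule that
multiplies the learning rate by 0.2 after 3 consecutive epochs without a
strictly lower validation loss, floored at 1e-5.

Because negatives outnumber positives by up to thousands to one in
off-target screens, the headline metric is the area under the
precision–recall curve (non-interpolated average precision); ROC-AUC,
recall and precision are reported alongside.  Both AUCs are implemented
here from first principles (rank statistic / threshold sweep) so they can
be cross-checked against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .encoding import TokenTable, encode_dataset
from .io_data import Dataset
from .model import HybridNetwork, ModelSpec, build_model
from .nn import Adam, no_grad, softmax_cross_entropy


class StratificationError(ValueError):
    """A class has fewer members than the requested number of folds."""


class MetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainConfig:
    """Optimisation protocol constants (defaults are the published settings)."""

    initial_lr: float = 0.003
    plateau_patience: int = 3
    plateau_factor: float = 0.2
    min_lr: float = 1e-5
    epochs: int = 30
    batch_size: int = 512
    folds: int = 5
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr cannot exceed initial_lr")
        if self.epochs < 1 or self.batch_size < 1 or self.folds < 2:
            raise ValueError("epochs, batch_size >= 1 and folds >= 2 required")


class PlateauLRSchedule:
    """Reduce-on-plateau: lr ← max(lr × factor, min_lr) after `patience`
    consecutive epochs without a strictly lower monitored loss."""

    def __init__(self, config: TrainConfig):
        self.lr = config.initial_lr
        self.factor = config.plateau_factor
        self.patience = config.plateau_patience
        self.min_lr = config.min_lr
        self.best = math.inf
        self.wait = 0

    def step(self, monitored_loss: float) -> float:
        if monitored_loss < self.best:
            self.best = monitored_loss
            self.wait = 0
        else:  # equal counts as no improvement
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


# ---------------------------------------------------------------------------
# splits


def stratified_kfold_split(
    labels: Sequence[int] | np.ndarray, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Shuffled stratified k-fold partition of sample indices.

    Returns k disjoint held-out index arrays covering every sample; per-fold
    counts of each class differ by at most 1 across folds.
    """
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls} has {len(idx)} member(s), fewer than k={k}"
            )
        rng.shuffle(idx)
        for fold, chunk in zip(folds, np.array_split(idx, k)):
            fold.extend(chunk.tolist())
    return [np.sort(np.asarray(f)) for f in folds]


# ---------------------------------------------------------------------------
# metrics


def compute_roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC as the Mann–Whitney rank statistic: the probability a random
    positive outscores a random negative, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC-AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Non-interpolated average precision: Σ precisionᵢ · (recallᵢ − recallᵢ₋₁)
    over descending unique score thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise MetricError("PR-AUC undefined: no positive samples")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # evaluate only at the last index of each tied-score run
    threshold_idx = np.flatnonzero(np.diff(np.append(sorted_scores, np.nan)) != 0)
    precision = tp[threshold_idx] / (tp[threshold_idx] + fp[threshold_idx])
    recall = tp[threshold_idx] / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum(precision * (recall - recall_prev)))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    predicted: Sequence[int] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    return ConfusionCounts(
        tp=int(((predicted == 1) & (labels == 1)).sum()),
        fp=int(((predicted == 1) & (labels == 0)).sum()),
        tn=int(((predicted == 0) & (labels == 0)).sum()),
        fn=int(((predicted == 0) & (labels == 1)).sum()),
    )


def compute_recall_precision(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(recall, precision) = (TP/(TP+FN), TP/(TP+FP)); None when undefined."""
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    return recall, precision


@dataclass
class Metrics:
    pr_auc: float
    roc_auc: float
    recall: float | None
    precision: float | None

    def as_dict(self) -> dict:
        return {
            "pr_auc": self.pr_auc,
            "roc_auc": self.roc_auc,
            "recall": self.recall,
            "precision": self.precision,
        }


def evaluate(model: HybridNetwork, tokens: np.ndarray, labels: np.ndarray) -> Metrics:
    """Score a model on encoded pairs: AUCs from the active-class probability,
    recall/precision from the argmax decision."""
    probs = model.predict(tokens)[:, 1]
    predicted = (probs >= 0.5).astype(int)
    recall, precision = compute_recall_precision(confusion_counts(predicted, labels))
    return Metrics(
        pr_auc=compute_pr_auc(probs, labels),
        roc_auc=compute_roc_auc(probs, labels),
        recall=recall,
        precision=precision,
    )


def mean_metrics(fold_metrics: Sequence[Metrics]) -> Metrics:
    def _mean(values):
        present = [v for v in values if v is not None]
        return float(np.mean(present)) if present else None

    return Metrics(
        pr_auc=_mean([m.pr_auc for m in fold_metrics]),
        roc_auc=_mean([m.roc_auc for m in fold_metrics]),
        recall=_mean([m.recall for m in fold_metrics]),
        precision=_mean([m.precision for m in fold_metrics]),
    )


# ---------------------------------------------------------------------------
# training loops


def _onehot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), 2), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def train_model(
    model: HybridNetwork,
    train_tokens: np.ndarray,
    train_labels: np.ndarray,
    val_tokens: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig,
    seed: int = 0,
) -> dict:
    """Minibatch-train one model; returns per-epoch history (losses, lr)."""
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=config.initial_lr)
    schedule = PlateauLRSchedule(config)
    val_onehot = _onehot(val_labels)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    n = len(train_tokens)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            logits = model.forward(train_tokens[batch], train=True)
            loss = softmax_cross_entropy(logits, _onehot(train_labels[batch]))
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
        val_loss = 0.0
        with no_grad():
            for start in range(0, len(val_tokens), 4096):
                chunk = slice(start, start + 4096)
                logits = model.forward(val_tokens[chunk], train=False)
                loss = softmax_cross_entropy(logits, val_onehot[chunk])
                val_loss += float(loss.data) * (len(val_onehot[chunk]))
        val_loss /= len(val_tokens)
        optimizer.lr = schedule.step(val_loss)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(optimizer.lr)
    return history


@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    mean: Metrics
    histories: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "folds": [m.as_dict() for m in self.fold_metrics],
            "mean": self.mean.as_dict(),
        }


def cross_validate(
    dataset: Dataset,
    spec: ModelSpec | None = None,
    variant: str = "full",
    config: TrainConfig | None = None,
    table: TokenTable | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of one variant on one dataset.

    Each fold's held-out part serves both as the plateau-monitoring
    validation set and as the evaluation set, mirroring the published
    protocol; the token encoder is applied identically to every fold.
    """
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    tokens = encode_dataset(dataset.pairs, table)
    labels = np.asarray(dataset.labels())
    folds = stratified_kfold_split(labels, k=config.folds, seed=config.shuffle_seed)
    all_idx = np.arange(len(labels))
    fold_metrics: list[Metrics] = []
    histories: list[dict] = []
    for fold_no, held_out in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, held_out)
        model = build_model(spec, variant, seed=config.shuffle_seed * 1000 + fold_no)
        history = train_model(
            model,
            tokens[train_idx],
            labels[train_idx],
            tokens[held_out],
            labels[held_out],
            config,
            seed=config.shuffle_seed * 1000 + 500 + fold_no,
        )
        fold_metrics.append(evaluate(model, tokens[held_out], labels[held_out]))
        histories.append(history)
    return CVResult(fold_metrics, mean_metrics(fold_metrics), histories)


def generalization_run(
    train_sets: Sequence[Dataset],
    test_sets: Sequence[Dataset],
    spec: ModelSpec | None = None,
    variant: str = "full",
    config: TrainConfig | None = None,
    table: TokenTable | None = None,
) -> Metrics:
    """Train once on pooled training datasets, evaluate once on the pooled
    held-out datasets (cross-technique transfer design)."""
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    train_pool = Dataset.concatenate(train_sets, name="train_pool")
    test_pool = Dataset.concatenate(test_sets, name="test_pool")
    if not len(train_pool) or not len(test_pool):
        raise ValueError("train and test pools must be nonempty")
    train_tokens = encode_dataset(train_pool.pairs, table)
    train_labels = np.asarray(train_pool.labels())
    test_tokens = encode_dataset(test_pool.pairs, table)
    test_labels = np.asarray(test_pool.labels())
    # carve a stratified tenth of the training pool for plateau monitoring
    folds = stratified_kfold_split(train_labels, k=10, seed=config.shuffle_seed)
    val_idx = folds[0]
    fit_idx = np.setdiff1d(np.arange(len(train_labels)), val_idx)
    model = build_model(spec, variant, seed=config.shuffle_seed)
    train_model(
        model,
        train_tokens[fit_idx],
        train_labels[fit_idx],
        train_tokens[val_idx],
        train_labels[val_idx],
        config,
        seed=config.shuffle_seed + 7,
    )
    return evaluate(model, test_tokens, test_labels)
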