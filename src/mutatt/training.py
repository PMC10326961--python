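"""Cross-validation, SGD training, ensembling and evaluation metrics.

Training follows a one-tumour-per-step regime (minibatch size 1) with plain
SGD plus momentum, minimizing cross-entropy. Catalogues larger than the
per-tumour mutation cap are subsampled anew each epoch. Ten-fold
cross-validation is stratified within each tumour type; one winning model
per fold (best validation top-1 accuracy) is combined into an ensemble by
summing component logits. The concatenated component logit vectors serve as
tumour-level features (n_components x n_classes values, e.g. 10 x 24 = 240).
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import TokenizedCatalogue
from .model import (
    ModelConfig,
    MutationSetClassifier,
    TumourPrediction,
    predict,
    subsample_catalogue,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """k disjoint folds covering all samples, balanced within each class."""

    folds: list[list[str]]
    labels: dict[str, str]

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_validation(self, i: int) -> tuple[list[str], list[str]]:
        val = self.folds[i]
        train = [s for j, fold in enumerate(self.folds) if j != i for s in fold]
        return train, val


def stratified_folds(labels: Mapping[str, str], k: int, seed: int) -> FoldSplit:
    """Split samples into k folds within each class (deterministic given seed).

    Within every class the fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    from sklearn.model_selection import StratifiedKFold

    samples = sorted(labels)
    y = [labels[s] for s in samples]
    counts = pd.Series(y).value_counts()
    small = counts[counts < k]
    if len(small):
        logger.warning("classes with fewer than %d samples: %s", k, dict(small))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, (_, val_idx) in enumerate(skf.split(samples, y)):
        folds[i] = [samples[j] for j in val_idx]
    return FoldSplit(folds, dict(labels))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 6e-4
    momentum: float = 0.9
    minibatch_size: int = 1  # one tumour per SGD step
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.momentum < 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.minibatch_size != 1:
            raise ValueError("only minibatch size 1 is supported")


@dataclass
class TrainResult:
    model: MutationSetClassifier
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float


def _label_index(tc: TokenizedCatalogue, class_labels: Sequence[str]) -> int:
    if tc.class_label is None:
        raise ValueError(f"catalogue {tc.sample_id} has no class label")
    return class_labels.index(tc.class_label)


def evaluate_top1(
    model: MutationSetClassifier, data: Sequence[TokenizedCatalogue], seed: int = 0
) -> float:
    if not data:
        return float("nan")
    labels = model.config.class_labels
    correct = 0
    for tc in data:
        p = predict(tc, model, seed=seed)
        correct += int(labels[p.predicted_index] == tc.class_label)
    return correct / len(data)


def train(
    model_config: ModelConfig,
    train_set: Sequence[TokenizedCatalogue],
    validation_set: Sequence[TokenizedCatalogue],
    train_config: TrainConfig | None = None,
) -> TrainResult:
    """SGD with momentum, one tumour per step; returns the best-validation model.

    Per-tumour subsamples above the mutation cap are re-drawn every epoch.
    Divergence (non-finite loss) aborts with diagnostics.
    """
    tcfg = train_config or TrainConfig()
    ss = np.random.SeedSequence(tcfg.seed)
    init_seed, order_seed, sub_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    model = MutationSetClassifier(model_config, seed=init_seed)
    labels = model_config.class_labels
    if labels is None:
        raise ValueError("model_config.class_labels is required for training")
    y_train = [_label_index(tc, labels) for tc in train_set]

    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    order_rng = np.random.default_rng(order_seed)
    sub_rng = np.random.default_rng(sub_seed)

    best_params = {k: v.copy() for k, v in model.params.items()}
    best_acc, best_epoch = -1.0, 0
    rows = []
    if tcfg.epochs == 0:
        acc = evaluate_top1(model, validation_set)
        history = pd.DataFrame([{"epoch": 0, "train_loss": np.nan, "val_accuracy": acc}])
        return TrainResult(model, history, 0, acc)

    for epoch in range(1, tcfg.epochs + 1):
        order = order_rng.permutation(len(train_set))
        losses = []
        for idx in order:
            tc = subsample_catalogue(train_set[idx], model_config.max_mutations, sub_rng)
            try:
                loss, grads, _ = model.loss_and_grads(tc.tokens(), y_train[idx])
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"training diverged at epoch {epoch} on sample {tc.sample_id}: {exc}"
                ) from exc
            losses.append(loss)
            for name, g in grads.items():
                v = velocity[name]
                v *= tcfg.momentum
                v += g
                model.params[name] -= tcfg.learning_rate * v
        val_acc = evaluate_top1(model, validation_set, seed=tcfg.seed)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    return TrainResult(model, pd.DataFrame(rows), best_epoch, best_acc)


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------

#: the full per-mutation-combo search grid: 3 x 3 x 2 x 2 = 36 configurations
DEFAULT_GRID = {
    "embedding_dim": (128, 256, 512),
    "n_encoder_layers": (1, 2, 4),
    "n_heads": (1, 2),
    "n_fc_layers": (1, 2),
}


def expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def hyperparameter_search(
    grid: Sequence[dict],
    catalogues: Mapping[str, TokenizedCatalogue],
    fold_split: FoldSplit,
    base_config: ModelConfig,
    train_config: TrainConfig | None = None,
) -> tuple["EnsembleModel", pd.DataFrame]:
    """Sweep configurations per fold; the best validation accuracy wins.

    Ties break towards fewer parameters, then earlier grid order. Returns the
    per-fold winners as an ensemble plus a report with one row per winner.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    winners, rows = [], []
    for fold_i in range(fold_split.k):
        train_ids, val_ids = fold_split.train_validation(fold_i)
        train_set = [catalogues[s] for s in train_ids]
        val_set = [catalogues[s] for s in val_ids]
        best = None
        for gi, overrides in enumerate(grid):
            cfg = copy.deepcopy(base_config)
            for key, value in overrides.items():
                setattr(cfg, key, value)
            cfg.__post_init__()
            result = train(cfg, train_set, val_set, train_config)
            n_par = result.model.n_parameters()
            key = (-result.best_val_accuracy, n_par, gi)
            if best is None or key < best[0]:
                best = (key, result, overrides, n_par)
        _, result, overrides, n_par = best
        winners.append(result.model)
        rows.append({"fold": fold_i, "val_accuracy": result.best_val_accuracy,
                     "n_parameters": n_par, **overrides})
    return EnsembleModel(winners), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ensembling
# ---------------------------------------------------------------------------


class EnsembleModel:
    """Ordered component models; prediction sums the component logits."""

    def __init__(self, components: Sequence[MutationSetClassifier]):
        if not components:
            raise ValueError("ensemble needs at least one component")
        ref = components[0].config
        for c in components[1:]:
            if c.config.n_classes != ref.n_classes or c.config.class_labels != ref.class_labels:
                raise ValueError("ensemble components disagree on the class set")
        self.components = list(components)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def class_labels(self) -> list[str] | None:
        return self.components[0].config.class_labels

    def component_logits(self, catalogue: TokenizedCatalogue, seed: int = 0) -> np.ndarray:
        """(n_components, n_classes) logits; the subsample is shared across components."""
        rng = np.random.default_rng(seed)
        cap = min(c.config.max_mutations for c in self.components)
        sub = subsample_catalogue(catalogue, cap, rng)
        return np.vstack([c.logits(sub.tokens())[0] for c in self.components])


def ensemble_predict(
    ensemble: EnsembleModel, catalogue: TokenizedCatalogue, seed: int = 0
) -> tuple[TumourPrediction, np.ndarray]:
    """Summed-logit ensemble prediction plus the concatenated feature vector."""
    block = ensemble.component_logits(catalogue, seed)
    prediction = TumourPrediction.from_logits(
        catalogue.sample_id, block.sum(axis=0), ensemble.class_labels,
        true_label=catalogue.class_label,
    )
    return prediction, block.ravel()


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def topk_metrics(
    scores: np.ndarray, labels: Sequence[int], k_list: Iterable[int] = (1, 3, 5)
) -> dict:
    """Accuracy/top-k, per-class precision, recall, F1 and the confusion matrix.

    ``scores`` is (n_samples, n_classes); rows of the confusion matrix are the
    true class. Precision of a class that is never predicted is reported as 0
    and flagged in ``undefined_precision``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, C = scores.shape
    order = np.argsort(-scores, axis=1)
    topk = {}
    for k in k_list:
        kk = min(k, C)
        topk[k] = float(np.mean([labels[i] in order[i, :kk] for i in range(n)]))
    pred = order[:, 0]
    cm = np.zeros((C, C), dtype=int)
    for t, p in zip(labels, pred):
        cm[t, p] += 1
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    return {
        "accuracy": float(np.mean(pred == labels)),
        "topk": topk,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "confusion_matrix": cm,
        "undefined_precision": np.where(tp + fp == 0)[0].tolist(),
    }


def calibration_and_stability(
    probabilities: np.ndarray,
    labels: Sequence[int],
    n_bins: int = 10,
    repeat_predictions: np.ndarray | None = None,
) -> dict:
    """Reliability bins (equal-width confidence) and per-tumour repeat agreement.

    ``repeat_predictions`` is an optional (n_samples, n_repeats) array of
    predicted class indices from repeated subsampled predictions; stability is
    the per-sample fraction of repeats agreeing with the modal prediction.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    conf = probabilities.max(axis=1)
    pred = probabilities.argmax(axis=1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (conf > lo) & (conf <= hi) if b else (conf >= lo) & (conf <= hi)
        rows.append(
            {
                "bin": b,
                "lower": lo,
                "upper": hi,
                "count": int(mask.sum()),
                "mean_confidence": float(conf[mask].mean()) if mask.any() else np.nan,
                "accuracy": float((pred[mask] == labels[mask]).mean()) if mask.any() else np.nan,
            }
        )
    out = {"calibration": pd.DataFrame(rows)}
    if repeat_predictions is not None:
        rp = np.asarray(repeat_predictions, dtype=int)
        stability = []
        for row in rp:
            modal = np.bincount(row).argmax()
            stability.append(float(np.mean(row == modal)))
        out["stability"] = np.array(stability)
    return out


def downsampling_curve(
    ensemble: EnsembleModel,
    test_set: Sequence[TokenizedCatalogue],
    n_list: Sequence[int] = (10, 50, 100, 300, 1000, 2500, 4000, 5000),
    seed: int = 0,
    k_list: Iterable[int] = (1, 3, 5),
) -> pd.DataFrame:
    """Accuracy versus the number of mutations kept per tumour.

    For each n, min(n, catalogue size) mutations are subsampled (seeded) and
    the ensemble scored at top-k.
    """
    labels = ensemble.class_labels
    rows = []
    for n in n_list:
        rng = np.random.default_rng(np.random.SeedSequence((seed, int(n))))
        scores, ys = [], []
        for tc in test_set:
            sub = subsample_catalogue(tc, n, rng)
            pred, _ = ensemble_predict(ensemble, sub, seed=seed)
            scores.append(pred.logits)
            ys.append(labels.index(tc.class_label))
        metrics = topk_metrics(np.vstack(scores), ys, k_list)
        rows.append({"n": n, **{f"top{k}": v for k, v in metrics["topk"].items()}})
    return pd.DataFrame(rows)
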