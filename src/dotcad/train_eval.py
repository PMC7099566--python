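"""Training loop and evaluation suite for the slice classifier.

Training is mini-batch stochastic gradient descent with momentum
(v <- m*v - lr*g; p <- p + v), a seeded per-epoch shuffle, and early
stopping on the misclassification rate (MCR) of a monitored set: when the
monitored MCR has not improved for ``patience`` consecutive epochs,
training stops and the parameters from the best epoch are restored.
Monitoring the test set reproduces the original protocol but leaks test
information into the stopping decision; pass a held-out validation set as
``monitor_set`` to avoid that.

Evaluation covers the 2x2 confusion table with sensitivity/specificity/
accuracy (malignant = positive class), a threshold-sweep ROC curve whose
trapezoidal area equals the Mann-Whitney U statistic with half credit for
ties, a learning-rate sweep, and stratified k-fold cross-validation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from dotcad import net
from dotcad.net import NetworkParams
from dotcad.phantom import BENIGN, MALIGNANT
from dotcad.preprocess import SliceImage, as_arrays

#: one-hot columns: index 0 = malignant (1,0), index 1 = benign (0,1)
CLASS_INDEX = {MALIGNANT: 0, BENIGN: 1}
INDEX_CLASS = {v: k for k, v in CLASS_INDEX.items()}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.3
    batch_size: int = 83
    max_epochs: int = 500
    momentum: float = 0.9
    patience: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch-norm constraint)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    train_mcr: list[float] = field(default_factory=list)
    monitor_mcr: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based; earliest epoch attaining the minimal monitored MCR
    stopped_early: bool = False


@dataclass
class EvalReport:
    """Confusion counts, derived proportions, and the ROC curve.

    Malignant is the positive class. A metric whose denominator is zero
    (its class absent from the truth) is None — undefined, not 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    roc_points: Optional[list[tuple[float, float]]] = None
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "roc_points": self.roc_points,
        }


def one_hot(labels: Sequence[str]) -> np.ndarray:
    out = np.zeros((len(labels), 2))
    for i, lab in enumerate(labels):
        out[i, CLASS_INDEX[lab]] = 1.0
    return out


def sgd_momentum_step(
    params: NetworkParams,
    grads: dict[str, np.ndarray],
    velocity: dict[str, np.ndarray],
    learning_rate: float,
    momentum: float,
) -> None:
    """In-place momentum update over every learnable array."""
    for name in NetworkParams.LEARNABLE:
        g = grads[name]
        p = getattr(params, name)
        if g.shape != p.shape or velocity[name].shape != p.shape:
            raise ValueError(f"shape mismatch for {name}")
        velocity[name] = momentum * velocity[name] - learning_rate * g
        setattr(params, name, p + velocity[name])


def zero_velocity(params: NetworkParams) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(getattr(params, name)) for name in NetworkParams.LEARNABLE}


def predict(params: NetworkParams, images: Sequence[SliceImage] | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Inference-mode scores and hard labels.

    The score is the softmax probability of malignancy; the hard label is
    the argmax with ties resolved to benign (the conservative choice for
    a screening follow-up decision is debatable either way; the rule here
    is simply fixed and documented).
    """
    if isinstance(images, np.ndarray):
        x = images
    else:
        x, _ = as_arrays(images)
    probs, _ = net.forward(params, x, mode="infer")
    scores = probs[:, CLASS_INDEX[MALIGNANT]]
    labels = [MALIGNANT if s > 0.5 else BENIGN for s in scores]
    return scores, labels


def mcr(params: NetworkParams, images: Sequence[SliceImage]) -> float:
    """Misclassification rate of the hard predictions on a labelled set."""
    _, pred = predict(params, images)
    truth = [img.label for img in images]
    return float(np.mean([p != t for p, t in zip(pred, truth)]))


def train(
    params: NetworkParams,
    train_set: Sequence[SliceImage],
    monitor_set: Sequence[SliceImage],
    config: TrainConfig,
    monitor_fn: Optional[Callable[[NetworkParams], float]] = None,
) -> tuple[NetworkParams, TrainHistory]:
    """Train with SGD momentum and MCR early stopping.

    Each epoch shuffles the training images with a generator seeded from
    ``config.seed``; a final short batch is kept when it holds at least
    two samples (batch normalization is defined) and dropped otherwise.
    After each epoch the monitored MCR is computed (``monitor_fn``
    overrides the default evaluation on ``monitor_set``, e.g. for a
    custom monitoring metric); training stops when it has not strictly
    improved for ``config.patience`` epochs, and the best-epoch
    parameters are returned.
    """
    config.validate()
    if len(train_set) == 0 or len(monitor_set) == 0:
        raise ValueError("train and monitor sets must be non-empty")
    params = params.copy()
    velocity = zero_velocity(params)
    rng = np.random.default_rng(config.seed)
    x_all, y_lab = as_arrays(train_set)
    y_all = one_hot(y_lab)
    n = x_all.shape[0]
    history = TrainHistory()
    best_mcr = np.inf
    best_params = params.copy()
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        n_wrong = 0
        n_seen = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # an orphan sample cannot be batch-normalized
            probs, cache = net.forward(params, x_all[idx], mode="train")
            loss, d_logits = net.cross_entropy_loss(probs, y_all[idx])
            grads = net.backward(params, cache, d_logits)
            sgd_momentum_step(params, grads, velocity, config.learning_rate, config.momentum)
            epoch_loss += loss
            n_batches += 1
            # train MCR accumulated from the mini-batch forward passes
            # (batch statistics), avoiding a second pass over the set
            n_wrong += int((probs.argmax(axis=1) != y_all[idx].argmax(axis=1)).sum())
            n_seen += idx.size
        history.loss.append(epoch_loss / max(n_batches, 1))
        history.train_mcr.append(n_wrong / max(n_seen, 1))
        monitored = monitor_fn(params) if monitor_fn is not None else mcr(params, monitor_set)
        history.monitor_mcr.append(monitored)
        if monitored < best_mcr:
            best_mcr = monitored
            best_params = params.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if since_best >= config.patience:
            history.stopped_early = True
            break
    return best_params, history


def confusion_metrics(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> EvalReport:
    """2x2 confusion table with malignant as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    for lab in list(true_labels) + list(predicted_labels):
        if lab not in CLASS_INDEX:
            raise ValueError(f"unknown label {lab!r}")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == MALIGNANT:
            tp += p == MALIGNANT
            fn += p == BENIGN
        else:
            tn += p == BENIGN
            fp += p == MALIGNANT
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / total if total else None
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec, accuracy=acc)


def roc_auc(scores: Sequence[float], true_labels: Sequence[str]) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Thresholds run over the unique scores (descending) plus a sentinel so
    the curve starts at (0,0) and ends at (1,1) and is coordinatewise
    nondecreasing. Tied scores move the operating point diagonally, so
    the trapezoidal area equals the Mann-Whitney probability that a
    random malignant case outranks a random benign one, with half credit
    for ties.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([lab == MALIGNANT for lab in true_labels])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        pred_pos = scores >= t
        tpr = float((pred_pos & y).sum() / n_pos)
        fpr = float((pred_pos & ~y).sum() / n_neg)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def evaluate(params: NetworkParams, images: Sequence[SliceImage]) -> EvalReport:
    """Predict a labelled set and assemble the full report, ROC included."""
    scores, pred = predict(params, images)
    truth = [img.label for img in images]
    report = confusion_metrics(truth, pred)
    if len(set(truth)) == 2:
        report.roc_points, report.auc = roc_auc(scores, truth)
    return report


def learning_rate_sweep(
    base_config: TrainConfig,
    rates: Sequence[float],
    train_set: Sequence[SliceImage],
    test_set: Sequence[SliceImage],
    init_seed: int = 0,
) -> list[EvalReport]:
    """Train one model per learning rate under a common seed and split."""
    if len(rates) == 0:
        raise ValueError("rate list must be non-empty")
    reports = []
    for lr in rates:
        cfg = TrainConfig(
            learning_rate=lr,
            batch_size=base_config.batch_size,
            max_epochs=base_config.max_epochs,
            momentum=base_config.momentum,
            patience=base_config.patience,
            seed=base_config.seed,
        )
        params0 = net.init_params(init_seed)
        trained, _ = train(params0, train_set, test_set, cfg)
        reports.append(evaluate(trained, test_set))
    return reports


def stratified_fold_indices(labels: Sequence[str], k: int, seed: int) -> list[np.ndarray]:
    """Class-stratified partition of indices into k folds (round-robin)."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in sorted(set(labels)):
        members = np.array([i for i, lab in enumerate(labels) if lab == label])
        members = members[rng.permutation(len(members))]
        for j, idx in enumerate(members):
            folds[j % k].append(int(idx))
    return [np.array(sorted(f)) for f in folds]


def kfold_cv(
    dataset: Sequence[SliceImage],
    k: int,
    config: TrainConfig,
    seed: int = 0,
    init_seed: int = 0,
) -> tuple[list[EvalReport], dict[str, float]]:
    """Stratified k-fold cross-validation.

    Each fold serves once as the test (and early-stopping monitor) set.
    Returns the per-fold reports and the mean and standard deviation
    (population, across folds) of accuracy and AUC.
    """
    labels = [img.label for img in dataset]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(counts.values(), default=0) < k:
        raise ValueError(f"k={k} exceeds the minority class count {min(counts.values())}")
    folds = stratified_fold_indices(labels, k, seed)
    reports = []
    for fold_idx in folds:
        test_set = [dataset[i] for i in fold_idx]
        train_set = [img for i, img in enumerate(dataset) if i not in set(fold_idx.tolist())]
        params0 = net.init_params(init_seed)
        trained, _ = train(params0, train_set, test_set, config)
        reports.append(evaluate(trained, test_set))
    accs = np.array([r.accuracy for r in reports], dtype=float)
    aucs = np.array([r.auc for r in reports], dtype=float)
    summary = {
        "accuracy_mean": float(accs.mean()),
        "accuracy_std": float(accs.std()),
        "auc_mean": float(aucs.mean()),
        "auc_std": float(aucs.std()),
    }
    return reports, summary
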