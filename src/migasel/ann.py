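"""Feedforward neural-network classification of feature vectors.

A single-hidden-layer perceptron (tanh hidden units, softmax output,
cross-entropy loss) separates left from right hand imagery.  Data are
split into training / validation / testing sets; training is full-batch
Adam, stopped when the validation loss stops improving, and the weights
from the best validation epoch are restored.  Features are z-scored with
statistics of the training split only.  "left" is the positive class
everywhere, and an exact 0.5 posterior is broken toward "left" so runs
are deterministic.

The trainer is a compact numpy implementation: the GA wrapper retrains
the network for every candidate feature subset, so a single fit must cost
milliseconds on 100-trial problems.

Two evaluation protocols are provided: a stratified holdout split and a
K-fold rotation in which, for each of the K turns, K-2 folds train the
network, one fold validates (early stopping) and one fold tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

POSITIVE_CLASS = "left"
NEGATIVE_CLASS = "right"


@dataclass(frozen=True)
class AnnConfig:
    hidden_units: int = 7
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    standardize: bool = True
    learning_rate: float = 1e-2
    weight_decay: float = 1e-3  # L2 on weights; keeps noise inputs from
    # acting as implicit regularizers, which matters for wrapper selection

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Holdout fractions or K-fold count, with the shuffling seed."""

    mode: str = "holdout"
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    K: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "holdout":
            total = self.train_frac + self.val_frac + self.test_frac
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"holdout fractions sum to {total}, expected 1")
        elif self.K < 3:
            raise ValueError("K-fold rotation needs K >= 3 (train K-2, val 1, test 1)")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with left as the positive class."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TP + other.TP, self.FN + other.FN,
                               self.FP + other.FP, self.TN + other.TN)


@dataclass(frozen=True)
class Metrics:
    """Confusion-derived proportions; NaN marks an undefined (0/0) metric."""

    sensitivity: float
    specificity: float
    precision_left: float
    precision_right: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision_left": self.precision_left,
            "precision_right": self.precision_right,
            "accuracy": self.accuracy,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP)
    per predicted class, and accuracy (TP+TN)/total.

    A zero denominator yields NaN for that metric, never a silent 0.
    """
    return Metrics(
        sensitivity=_ratio(cm.TP, cm.TP + cm.FN),
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        precision_left=_ratio(cm.TP, cm.TP + cm.FP),
        precision_right=_ratio(cm.TN, cm.TN + cm.FN),
        accuracy=_ratio(cm.TP + cm.TN, cm.total),
    )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = POSITIVE_CLASS
    return ConfusionMatrix(
        TP=int(np.sum((y_true == pos) & (y_pred == pos))),
        FN=int(np.sum((y_true == pos) & (y_pred != pos))),
        FP=int(np.sum((y_true != pos) & (y_pred == pos))),
        TN=int(np.sum((y_true != pos) & (y_pred != pos))),
    )


class _Standardizer:
    """Column z-scoring frozen on the training split; zero-variance guard."""

    def __init__(self, X_train: np.ndarray, enabled: bool = True):
        self.enabled = enabled
        if enabled:
            self.mean = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
            self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return X
        return (X - self.mean) / self.sd


class _MLP:
    """Tiny two-class MLP: tanh hidden layer, softmax output, full-batch Adam.

    Weight layout: W1 (d, h), b1 (h,), W2 (h, 2), b2 (2,).  Output column 0
    is the posterior of the positive ("left") class.
    """

    def __init__(self, n_features: int, hidden_units: int, seed: int):
        rng = np.random.default_rng(seed)
        h = hidden_units
        s1 = math.sqrt(2.0 / (n_features + h))
        s2 = math.sqrt(2.0 / (h + 2))
        self.W1 = rng.normal(0, s1, size=(n_features, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0, s2, size=(h, 2))
        self.b2 = np.zeros(2)

    # -- forward ---------------------------------------------------------
    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W1 + self.b1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self._hidden(X) @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def log_loss(self, X: np.ndarray, y01: np.ndarray) -> float:
        p = self.predict_proba(X)
        eps = 1e-12
        return float(-np.mean(np.log(p[np.arange(len(y01)), y01] + eps)))

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y01: np.ndarray, X_val: np.ndarray,
            yv01: np.ndarray, lr: float, max_epochs: int, patience: int,
            weight_decay: float = 0.0) -> int:
        """Adam on the cross-entropy; patience on validation loss; restores
        the best-validation weights.  Returns the number of epochs run."""
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(y01)
        onehot = np.zeros((n, 2))
        onehot[np.arange(n), y01] = 1.0
        best_loss = np.inf
        best_state = None
        stall = 0
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            H = self._hidden(X)
            P = self.predict_proba(X)
            dlogits = (P - onehot) / n
            gW2 = H.T @ dlogits
            gb2 = dlogits.sum(axis=0)
            dH = dlogits @ self.W2.T * (1.0 - H**2)
            gW1 = X.T @ dH
            gb1 = dH.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            t = epoch
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**t)
                vhat = vi / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
            if weight_decay:
                # decoupled decay on the weight matrices (not biases)
                self.W1 *= 1.0 - lr * weight_decay
                self.W2 *= 1.0 - lr * weight_decay
            val_loss = self.log_loss(X_val, yv01)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = [p.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        if best_state is not None:
            self.W1, self.b1, self.W2, self.b2 = best_state
        return epoch


@dataclass
class TrainedAnn:
    """Fitted network plus the split indices and per-phase confusion matrices."""

    model: _MLP
    scaler: _Standardizer
    split_indices: dict[str, np.ndarray]
    confusion: dict[str, ConfusionMatrix]
    epochs_run: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels with the 0.5 tie broken toward left."""
        proba = self.model.predict_proba(self.scaler(X))
        return np.where(proba[:, 0] >= 0.5, POSITIVE_CLASS, NEGATIVE_CLASS)

    def metrics(self) -> dict[str, Metrics]:
        return {phase: confusion_metrics(cm) for phase, cm in self.confusion.items()}


def holdout_indices(labels: Sequence[str], split: SplitSpec) -> dict[str, np.ndarray]:
    """Stratified train/validation/test index sets for a holdout split."""
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, train_size=split.train_frac, random_state=split.seed, stratify=y)
    rel_test = split.test_frac / (split.val_frac + split.test_frac)
    val_idx, test_idx = train_test_split(
        rest_idx, test_size=rel_test, random_state=split.seed + 1,
        stratify=y[rest_idx])
    return {"training": np.sort(train_idx), "validation": np.sort(val_idx),
            "testing": np.sort(test_idx)}


def _encode(y: np.ndarray) -> np.ndarray:
    """left -> 0 (positive), right -> 1."""
    return np.where(np.asarray(y) == POSITIVE_CLASS, 0, 1)


def train_ann(features: np.ndarray, labels: Sequence[str], cfg: AnnConfig,
              split: SplitSpec, mask: np.ndarray | None = None,
              indices: dict[str, np.ndarray] | None = None) -> TrainedAnn:
    """Train on a (masked) feature matrix; report per-phase confusion matrices.

    ``mask`` is an optional binary column selector (all columns when None);
    ``indices`` overrides the holdout split with explicit index sets.
    Deterministic for fixed config seeds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.size != X.shape[1]:
            raise ValueError(f"mask of {mask.size} genes for {X.shape[1]} columns")
        if not mask.any():
            raise ValueError("mask selects no features")
        X = X[:, mask]
    if indices is None:
        indices = holdout_indices(y, split)
    tr, va, te = indices["training"], indices["validation"], indices["testing"]
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split must contain both classes")
    scaler = _Standardizer(X[tr], enabled=cfg.standardize)
    model = _MLP(X.shape[1], cfg.hidden_units, cfg.seed)
    epochs = model.fit(scaler(X[tr]), _encode(y[tr]), scaler(X[va]),
                       _encode(y[va]), cfg.learning_rate, cfg.max_epochs,
                       cfg.patience, cfg.weight_decay)
    trained = TrainedAnn(model, scaler, dict(indices), {}, epochs)
    confusion: dict[str, ConfusionMatrix] = {}
    for phase, ids in (("training", tr), ("validation", va), ("testing", te)):
        confusion[phase] = confusion_from_predictions(y[ids], trained.predict(X[ids]))
    confusion["all"] = (confusion["training"] + confusion["validation"]
                        + confusion["testing"])
    trained.confusion = confusion
    return trained


def kfold_indices(labels: Sequence[str], K: int, seed: int) -> list[dict[str, np.ndarray]]:
    """K rotations of (train on K-2 folds, validate on 1, test on 1).

    Folds are stratified and differ in size by at most one sample; each
    sample is tested exactly once across the K rotations.
    """
    y = np.asarray(labels)
    if K > len(y) // 2:
        raise ValueError(f"K={K} too large for n={len(y)}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    rotations = []
    for r in range(K):
        test = folds[r]
        val = folds[(r + 1) % K]
        train = np.concatenate([folds[j] for j in range(K)
                                if j not in (r, (r + 1) % K)])
        rotations.append({"training": np.sort(train), "validation": np.sort(val),
                          "testing": np.sort(test)})
    return rotations


@dataclass
class KFoldResult:
    per_fold: list[dict[str, Metrics]]  # one {phase: Metrics} dict per rotation
    averages: dict[str, Metrics]

    def testing_accuracies(self) -> list[float]:
        return [fold["testing"].accuracy for fold in self.per_fold]


def average_metrics(metrics_list: Sequence[Metrics]) -> Metrics:
    """Arithmetic mean of each metric over folds (NaNs propagate)."""
    arrs = {k: np.array([m.as_dict()[k] for m in metrics_list])
            for k in metrics_list[0].as_dict()}
    return Metrics(**{k: float(np.mean(v)) for k, v in arrs.items()})


def kfold_evaluate(features: np.ndarray, labels: Sequence[str], cfg: AnnConfig,
                   K: int, seed: int, mask: np.ndarray | None = None) -> KFoldResult:
    """Run the K-fold rotation and average the per-fold metrics."""
    rotations = kfold_indices(labels, K, seed)
    per_fold = []
    for rot in rotations:
        trained = train_ann(features, labels, cfg, SplitSpec(mode="kfold", K=K),
                            mask=mask, indices=rot)
        per_fold.append(trained.metrics())
    phases = per_fold[0].keys()
    averages = {ph: average_metrics([f[ph] for f in per_fold]) for ph in phases}
    return KFoldResult(per_fold, averages)
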