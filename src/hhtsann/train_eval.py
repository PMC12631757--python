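"""Training loop, Leave-One-Subject-Out protocol and confusion metrics.

Evaluation follows the LOSO protocol: one fold per subject, the test fold
holding all and only that subject's epochs, so no subject identity leaks from
train to test. Within each fold a subject-level slice of the training set
(10% of training subjects, at least one) serves as validation for early
stopping. Confusion counts are pooled across folds for the headline
sensitivity/specificity/accuracy (MDD is the positive class); fold-averaged
percentages are reported alongside.

The optimizer is Adam on the cross-entropy loss with optional
inverse-frequency class weights. Everything is seeded and deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DimensionError, EmptyInputError, ProtocolError
from .network import HhtSannClassifier, NetworkConfig, features_for_epochset
from .signal_io import EpochSet

logger = logging.getLogger("hhtsann")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    """Confusion counts and derived percentages (MDD positive)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Counts and percentages from binary label vectors (1 = MDD)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise DimensionError("y_true and y_pred must be equal-length, non-empty")
    return Metrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass
class LearningCurve:
    """Per-training-epoch losses and accuracies."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings: Adam, lr 1e-3, batch 64, early stopping patience 5."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    seed: int = 42
    class_weighting: bool = True
    val_fraction: float = 0.10  # fraction of training *subjects* held out

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1:
            raise ProtocolError("lr must be > 0 and batch_size >= 1")


# ---------------------------------------------------------------------------
# LOSO split
# ---------------------------------------------------------------------------

def loso_split(es: EpochSet):
    """One (train, test) pair per subject; test holds only that subject."""
    subjects = es.subjects
    if len(subjects) < 2:
        raise ProtocolError("LOSO needs at least 2 distinct subjects")
    folds = []
    for sid in subjects:
        mask = es.subject_ids == sid
        folds.append((es.subset(~mask), es.subset(mask)))
    return folds


def shuffle_labels_subjectwise(es: EpochSet, seed: int) -> EpochSet:
    """Permute class labels across subjects (labels stay constant per subject)."""
    rng = np.random.default_rng(seed)
    subjects = es.subjects
    subj_labels = np.array([es.labels[es.subject_ids == s][0] for s in subjects])
    permuted = subj_labels[rng.permutation(len(subjects))]
    new = dict(zip(subjects, permuted))
    labels = np.array([new[str(s)] for s in es.subject_ids])
    return replace(es, labels=labels)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _class_weights(y: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones(y.size)
    w = np.ones(y.size)
    for c in (0, 1):
        n_c = np.sum(y == c)
        if n_c:
            w[y == c] = y.size / (2.0 * n_c)
    return w


def train_on_features(
    model: HhtSannClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    cfg: TrainConfig = TrainConfig(),
):
    """Fit SE/attention/head parameters on a precomputed feature tensor.

    Standardisation statistics are fitted on the training tensor only. Early
    stopping monitors validation loss with the configured patience and the
    best-validation parameters are restored; an empty validation set disables
    early stopping and the final parameters are kept.
    """
    if X_train.shape[0] == 0:
        raise EmptyInputError("empty training set")
    y_train = np.asarray(y_train, dtype=np.int64)
    model.fit_standardizer(X_train)
    weights = _class_weights(y_train, cfg.class_weighting)
    opt = _Adam(model.params, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    curve = LearningCurve()
    have_val = X_val is not None and len(X_val) > 0
    best_val = np.inf
    best_params = model.copy_params()
    since_improve = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_train))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            _, grads = model.loss_and_grads(X_train[idx], y_train[idx], weights[idx])
            opt.step(model.params, grads)
        train_loss, _ = model.loss_and_grads(X_train, y_train, weights)
        train_acc = float(np.mean(model.predict(X_train) == y_train))
        curve.train_loss.append(train_loss)
        curve.train_acc.append(train_acc)
        if have_val:
            val_loss, _ = model.loss_and_grads(X_val, y_val)
            val_acc = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
            curve.val_loss.append(val_loss)
            curve.val_acc.append(val_acc)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = model.copy_params()
                since_improve = 0
            else:
                since_improve += 1
            if since_improve >= cfg.patience:
                break
    if have_val:
        model.set_params(best_params)
    return model, curve


def train(
    model: HhtSannClassifier,
    train_epochs: EpochSet,
    val_epochs: EpochSet | None,
    cfg: TrainConfig = TrainConfig(),
):
    """Train on raw epoch sets: runs the HHT layer, then fits the network."""
    if train_epochs.n_epochs == 0:
        raise EmptyInputError("empty training set")
    X_train, index = features_for_epochset(train_epochs, model.cfg)
    model.channel_index = index
    X_val = y_val = None
    if val_epochs is not None and val_epochs.n_epochs > 0:
        X_val, _ = features_for_epochset(val_epochs, model.cfg)
        y_val = val_epochs.labels
    return train_on_features(model, X_train, train_epochs.labels, X_val, y_val, cfg)


# ---------------------------------------------------------------------------
# LOSO evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    subject: str
    metrics: Metrics
    y_true: np.ndarray
    y_pred: np.ndarray
    curve: LearningCurve


@dataclass
class LosoResult:
    folds: list[FoldResult]
    skipped: list[str]

    @property
    def pooled(self) -> Metrics:
        total = Metrics(0, 0, 0, 0)
        for f in self.folds:
            total = total + f.metrics
        return total

    @property
    def fold_averaged(self) -> dict:
        keys = ("sensitivity", "specificity", "accuracy")
        out = {}
        for key in keys:
            vals = [getattr(f.metrics, key) for f in self.folds]
            vals = [v for v in vals if np.isfinite(v)]
            out[key] = float(np.mean(vals)) if vals else float("nan")
        return out

    def subject_accuracy(self) -> float:
        """Fraction of held-out subjects whose majority-vote call is correct.

        The exchangeable unit of a LOSO protocol is the subject, so null
        calibration (shuffled labels) is assessed on this statistic.
        """
        hits = [
            float(np.mean(f.y_pred) >= 0.5) == float(f.y_true[0])
            for f in self.folds
        ]
        return float(np.mean(hits)) if hits else float("nan")


def evaluate_loso(
    es: EpochSet,
    cfg: TrainConfig = TrainConfig(),
    net_cfg: NetworkConfig = NetworkConfig(),
    features: np.ndarray | None = None,
) -> LosoResult:
    """Leave-One-Subject-Out evaluation with a fresh model per fold.

    The HHT layer is a fixed per-epoch transform, so the feature tensor is
    computed once for the whole epoch set and reused across folds (it may
    also be passed in precomputed); standardisation is still fitted per fold
    on that fold's training epochs only.
    """
    subjects = es.subjects
    if len(subjects) < 2:
        raise ProtocolError("LOSO needs at least 2 distinct subjects")
    if len(np.unique(es.labels)) < 2:
        raise ProtocolError("both classes must be present")
    if features is None:
        features, _ = features_for_epochset(es, net_cfg)
    subj_arr = np.asarray(es.subject_ids)
    rng = np.random.default_rng(cfg.seed)
    folds: list[FoldResult] = []
    skipped: list[str] = []
    for fold_i, sid in enumerate(subjects):
        test_mask = subj_arr == sid
        train_subjects = [s for s in subjects if s != sid]
        y_by_subject = {
            s: int(es.labels[subj_arr == s][0]) for s in train_subjects
        }
        if len(set(y_by_subject.values())) < 2:
            warnings.warn(f"fold {sid}: one class absent from training; skipped")
            skipped.append(sid)
            continue
        n_val = max(1, int(round(cfg.val_fraction * len(train_subjects))))
        val_subjects = set(
            rng.choice(train_subjects, size=n_val, replace=False).tolist()
        )
        # the validation slice must leave both classes in the training slice
        remaining = [y for s, y in y_by_subject.items() if s not in val_subjects]
        if len(set(remaining)) < 2:
            val_subjects = set()
        val_mask = np.isin(subj_arr, list(val_subjects))
        train_mask = ~test_mask & ~val_mask
        model = HhtSannClassifier(
            features.shape[-1], net_cfg, rng=cfg.seed + 1000 * (fold_i + 1)
        )
        model, curve = train_on_features(
            model,
            features[train_mask], es.labels[train_mask],
            features[val_mask] if val_mask.any() else None,
            es.labels[val_mask] if val_mask.any() else None,
            cfg,
        )
        y_true = es.labels[test_mask]
        y_pred = model.predict(features[test_mask])
        folds.append(
            FoldResult(
                subject=str(sid),
                metrics=confusion_metrics(y_true, y_pred),
                y_true=y_true,
                y_pred=y_pred,
                curve=curve,
            )
        )
        logger.info(
            "fold %s: n_test=%d acc=%.1f%% (%d train epochs)",
            sid, int(test_mask.sum()), folds[-1].metrics.accuracy,
            int(train_mask.sum()),
        )
    return LosoResult(folds=folds, skipped=skipped)
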