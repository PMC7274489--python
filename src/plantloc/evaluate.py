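"""Cross-validation, per-class statistics and Andrews-curve diagnostics.

Per-class metrics are computed from one-vs-rest confusion counts:
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/n, precision = TP/(TP+FP), rate of false predictions
RFP = FP/(TP+FP), error rate ER = (FP+FN)/n, and the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

All rates are reported as fractions in [0, 1] (multiply by 100 for
percent display); MCC lies in [−1, 1].  Any 0/0 case yields 0 and is
flagged as degenerate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from plantloc.features import EncoderRecipe, FeatureMatrix, encode_many
from plantloc.model import SVMConfig, OvRModel, train_ovr, predict

METRIC_NAMES = ("Sn", "Sp", "Acc", "Precision", "RFP", "ER", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class over one prediction set."""

    per_class: Mapping[str, tuple[int, int, int, int]]  # (TP, FP, TN, FN)
    n_total: int

    def __post_init__(self):
        for cls, (tp, fp, tn, fn) in self.per_class.items():
            if tp + fp + tn + fn != self.n_total:
                raise ValueError(f"counts for {cls!r} do not sum to n_total")


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n_test: int
    n_correct: int

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_test if self.n_test else 0.0


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled per-class metrics, overall accuracy and per-fold results."""

    per_class: Mapping[str, Mapping[str, float]]
    overall_accuracy: float
    counts: ConfusionCounts
    per_fold: tuple[FoldResult, ...] = ()
    regime: str | None = None
    degenerate: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "overall_accuracy": self.overall_accuracy,
            "per_class": {c: dict(m) for c, m in self.per_class.items()},
            "per_fold": [
                {"fold": f.fold, "n_test": f.n_test, "accuracy": f.accuracy}
                for f in self.per_fold
            ],
            "confusion": {
                c: dict(zip(("TP", "FP", "TN", "FN"), v))
                for c, v in self.counts.per_class.items()
            },
            "degenerate": {c: list(v) for c, v in self.degenerate.items()},
        }


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str], class_list: Sequence[str]
) -> ConfusionCounts:
    """Tally one-vs-rest confusion counts for each class."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    known = set(class_list)
    for lab in list(truth) + list(predicted):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class_list")
    t = np.asarray(truth)
    p = np.asarray(predicted)
    n = len(t)
    per_class = {}
    for cls in class_list:
        tp = int(np.count_nonzero((t == cls) & (p == cls)))
        fn = int(np.count_nonzero((t == cls) & (p != cls)))
        fp = int(np.count_nonzero((t != cls) & (p == cls)))
        tn = n - tp - fn - fp
        per_class[cls] = (tp, fp, tn, fn)
    return ConfusionCounts(per_class=per_class, n_total=n)


def _ratio(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
) -> tuple[dict[str, dict[str, float]], dict[str, tuple[str, ...]]]:
    """Compute the seven per-class statistics from confusion counts.

    Returns ``(per_class_metrics, degenerate_flags)`` where degenerate
    flags list the metrics whose denominator was zero (value set to 0).
    """
    per_class: dict[str, dict[str, float]] = {}
    degenerate: dict[str, tuple[str, ...]] = {}
    n = counts.n_total
    for cls, (tp, fp, tn, fn) in counts.per_class.items():
        flags: list[str] = []
        m = {
            "Sn": _ratio(tp, tp + fn, flags, "Sn"),
            "Sp": _ratio(tn, tn + fp, flags, "Sp"),
            "Acc": _ratio(tp + tn, n, flags, "Acc"),
            "Precision": _ratio(tp, tp + fp, flags, "Precision"),
            "RFP": _ratio(fp, tp + fp, flags, "RFP"),
            "ER": _ratio(fp + fn, n, flags, "ER"),
        }
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            flags.append("MCC")
            m["MCC"] = 0.0
        else:
            m["MCC"] = (tp * tn - fp * fn) / math.sqrt(denom)
        per_class[cls] = m
        if flags:
            degenerate[cls] = tuple(flags)
    return per_class, degenerate


def report_from_predictions(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_list: Sequence[str],
    per_fold: Sequence[FoldResult] = (),
    regime: str | None = None,
) -> EvaluationReport:
    """Build a full report (pooled confusion, metrics, accuracy) from
    parallel truth/prediction label lists."""
    counts = confusion_from_predictions(truth, predicted, class_list)
    per_class, degenerate = compute_metrics(counts)
    n_correct = int(np.count_nonzero(np.asarray(truth) == np.asarray(predicted)))
    return EvaluationReport(
        per_class=per_class,
        overall_accuracy=n_correct / counts.n_total if counts.n_total else 0.0,
        counts=counts,
        per_fold=tuple(per_fold),
        regime=regime,
        degenerate=degenerate,
    )


def cross_validate(
    records,
    labels: Sequence[str],
    recipe: EncoderRecipe,
    config: SVMConfig,
    k: int = 5,
    seed: int = 1,
    regime: str | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the OvR SVM pipeline.

    Features are encoded once; per fold the model is trained on k−1
    folds (standardizer refit each time) and the held-out fold is
    predicted.  Overall accuracy and per-class metrics come from the
    pooled predictions; per-fold accuracies are retained.

    A class with fewer than k members triggers scikit-learn's
    stratification warning; folds then simply lack that class.  A class
    whose training split holds fewer than 2 samples is excluded from
    that fold's model (its test samples still count as errors).
    """
    labels = list(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(labels):
        raise ValueError("k exceeds the number of samples")
    class_counts = {c: labels.count(c) for c in set(labels)}
    if min(class_counts.values()) < 2:
        bad = min(class_counts, key=class_counts.get)
        raise ValueError(f"class {bad!r} has fewer than 2 samples")
    if min(class_counts.values()) < k:
        warnings.warn(
            "some classes have fewer members than k; folds will not all "
            "contain every class",
            stacklevel=2,
        )

    X = encode_many(records, recipe)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    truth_all: list[str] = []
    pred_all: list[str] = []
    per_fold: list[FoldResult] = []
    for fold, (tr, te) in enumerate(skf.split(X.values, y)):
        y_tr = y[tr]
        fold_classes = tuple(
            c for c in config.class_list if np.count_nonzero(y_tr == c) >= 2
        )
        keep = np.isin(y_tr, fold_classes)
        fold_config = SVMConfig(
            C=config.C,
            class_list=fold_classes,
            recipe=recipe,
            gamma=config.gamma,
            sigma=config.sigma,
            class_weight=config.class_weight,
            seed=config.seed,
        )
        Xtr = FeatureMatrix(X.values[tr][keep], recipe)
        model = train_ovr(Xtr, y_tr[keep], fold_config)
        preds = predict(model, FeatureMatrix(X.values[te], recipe))
        truth_all.extend(y[te])
        pred_all.extend(p for p, _ in preds)
        n_correct = sum(1 for t_, (p_, _) in zip(y[te], preds) if t_ == p_)
        per_fold.append(FoldResult(fold=fold, n_test=len(te), n_correct=n_correct))

    return report_from_predictions(
        truth_all, pred_all, config.class_list, per_fold=per_fold, regime=regime
    )


def andrews_curves(
    features, labels: Sequence[str] | None = None, t_grid: Sequence[float] | None = None
) -> tuple[np.ndarray, tuple[str, ...], np.ndarray]:
    """Andrews curves for high-dimensional class-structure diagnostics.

    Each sample x is mapped to
    f_x(t) = x1/√2 + x2·sin t + x3·cos t + x4·sin 2t + x5·cos 2t + …,
    truncated at the feature dimension.

    Parameters
    ----------
    features : FeatureMatrix or (n, d) array
    labels : per-sample labels carried through for plotting
    t_grid : evaluation points, default 200 points over [−π, π]

    Returns ``(curves, labels, t_grid)`` with curves of shape
    ``(n_samples, len(t_grid))``.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("features must be a non-empty 2-d matrix")
    if t_grid is None:
        t_grid = np.linspace(-np.pi, np.pi, 200)
    t = np.asarray(t_grid, dtype=np.float64)
    if t.size == 0:
        raise ValueError("t_grid must be non-empty")
    n, d = X.shape
    basis = np.empty((d, len(t)))
    basis[0] = 1.0 / np.sqrt(2.0)
    for j in range(1, d):
        harmonic = (j + 1) // 2
        basis[j] = np.sin(harmonic * t) if j % 2 == 1 else np.cos(harmonic * t)
    curves = X @ basis
    lab = tuple(labels) if labels is not None else tuple("" for _ in range(n))
    if len(lab) != n:
        raise ValueError("labels length must match sample count")
    return curves, lab, t
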