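"""One-vs-rest RBF-kernel SVM multi-class predictor.

One binary SVM is trained per localization class (that class positive,
all others negative) on z-score standardized features; an unseen sample
is assigned the class whose binary classifier reports the highest signed
decision value, ties broken by class-list order.

The kernel width may be given directly as ``gamma`` or as ``sigma``
with the conventional mapping gamma = 1/(2·sigma²), matching
k(x, y) = exp(-||x - y||² / 2σ²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from plantloc.features import EncoderRecipe, FeatureMatrix

MODEL_FORMAT_VERSION = 1

#: Per-regime default hyperparameters for the best hybrid encoder
#: (PseAAC-NCC-DIPEP): single-label and combined models use sigma=50,
#: C=500; the dual-only model uses C=10, gamma=0.001.
REGIME_DEFAULTS = {
    "single": {"C": 500.0, "sigma": 50.0},
    "combined": {"C": 500.0, "sigma": 50.0},
    "dual": {"C": 10.0, "gamma": 0.001},
}


class ModelLoadError(RuntimeError):
    """Corrupt, truncated or incompatible model file."""


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters and class scheme for an OvR RBF-SVM ensemble."""

    C: float
    class_list: tuple[str, ...]
    recipe: EncoderRecipe
    gamma: float | None = None
    sigma: float | None = None
    class_weight: str | None = None  # None or "balanced"
    seed: int = 1

    def __post_init__(self):
        if (self.gamma is None) == (self.sigma is None):
            raise ValueError("supply exactly one of gamma or sigma")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.effective_gamma <= 0:
            raise ValueError("derived gamma must be positive")
        if len(set(self.class_list)) != len(self.class_list):
            raise ValueError("class_list entries must be distinct")

    @property
    def effective_gamma(self) -> float:
        if self.gamma is not None:
            return self.gamma
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class OvRModel:
    """A trained one-vs-rest ensemble with its standardization stats."""

    per_class_models: Mapping[str, SVC]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    config: SVMConfig

    def __post_init__(self):
        if set(self.per_class_models) != set(self.config.class_list):
            raise ValueError("per-class models must cover class_list exactly")
        if len(self.scaler_mean) != self.config.recipe.dimension:
            raise ValueError("standardizer dimension mismatch with recipe")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale


def train_ovr(
    features: FeatureMatrix, labels: Sequence[str], config: SVMConfig
) -> OvRModel:
    """Fit one binary RBF-SVM per class in ``config.class_list``.

    Features are z-score standardized with statistics from this
    training matrix only.  Every class must have at least two samples.
    """
    labels = list(labels)
    X = np.asarray(features.values, dtype=np.float64)
    if X.shape[0] != len(labels):
        raise ValueError(
            f"feature rows ({X.shape[0]}) != label count ({len(labels)})"
        )
    if X.shape[1] != config.recipe.dimension:
        raise ValueError("feature dimension does not match config recipe")
    unknown = set(labels) - set(config.class_list)
    if unknown:
        raise ValueError(f"label(s) outside class_list: {sorted(unknown)}")
    y = np.asarray(labels)
    for cls in config.class_list:
        if np.count_nonzero(y == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training samples")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    per_class: dict[str, SVC] = {}
    for cls in config.class_list:
        svc = SVC(
            kernel="rbf",
            C=config.C,
            gamma=config.effective_gamma,
            class_weight=config.class_weight,
            random_state=config.seed,
        )
        svc.fit(Xs, (y == cls).astype(int))
        per_class[cls] = svc
    return OvRModel(
        per_class_models=per_class,
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        config=config,
    )


def decision_matrix(model: OvRModel, features: FeatureMatrix) -> np.ndarray:
    """Signed decision values, shape (n_samples, n_classes) in
    class_list order; positive-class orientation."""
    X = np.asarray(features.values, dtype=np.float64)
    if X.shape[1] != model.config.recipe.dimension:
        raise ValueError("feature dimension does not match model recipe")
    Xs = model.standardize(X)
    cols = []
    for cls in model.config.class_list:
        svc = model.per_class_models[cls]
        d = svc.decision_function(Xs)
        # decision_function is oriented toward classes_[1]; flip if the
        # positive label (1) is first
        if svc.classes_[1] == 0:
            d = -d
        cols.append(d)
    return np.column_stack(cols)


def predict(
    model: OvRModel, features: FeatureMatrix
) -> list[tuple[str, dict[str, float]]]:
    """Predict each row's class: the argmax of per-class decision
    values (ties broken by class_list order), returned with the full
    score map."""
    D = decision_matrix(model, features)
    classes = model.config.class_list
    out = []
    for row in D:
        k = int(np.argmax(row))  # first max wins -> class_list order
        out.append((classes[k], {c: float(v) for c, v in zip(classes, row)}))
    return out


def save_model(model: OvRModel, path) -> None:
    """Serialize a trained ensemble (joblib archive with a format
    version; includes recipe, class list and standardizer)."""
    payload = {
        "format": "plantloc-ovr",
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config,
        "scaler_mean": model.scaler_mean,
        "scaler_scale": model.scaler_scale,
        "per_class_models": dict(model.per_class_models),
    }
    joblib.dump(payload, path)


def load_model(path) -> OvRModel:
    """Load a model saved by :func:`save_model`; corrupt or
    incompatible files raise :class:`ModelLoadError`."""
    try:
        payload = joblib.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ModelLoadError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "plantloc-ovr":
        raise ModelLoadError(f"{path} is not a plantloc model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    return OvRModel(
        per_class_models=payload["per_class_models"],
        scaler_mean=payload["scaler_mean"],
        scaler_scale=payload["scaler_scale"],
        config=payload["config"],
    )
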