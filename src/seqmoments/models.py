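"""Classifier backends (random forest, SVM, feed-forward net) under one
contract: seeded training, class-1 scores in [0, 1], feature-name checked
prediction, and JSON-sidecar persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__
from .features import FeatureMatrix

BACKENDS = ("rf", "svm", "nn")

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "rf": {"n_estimators": 100, "max_depth": None},
    "svm": {"kernel": "rbf", "C": 1.0},
    "nn": {"hidden_layer_sizes": (32,), "max_iter": 500},
}

# Trees are scale-invariant; margin- and gradient-based backends are not.
_DEFAULT_STANDARDIZE = {"rf": False, "svm": True, "nn": True}


@dataclass(frozen=True)
class ModelConfig:
    backend: str = "rf"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    standardize: bool | None = None  # None = backend default
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; expected {BACKENDS}")

    def resolved_hyperparameters(self) -> dict[str, Any]:
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.backend])
        merged.update(self.hyperparameters)
        return merged

    def resolved_standardize(self) -> bool:
        if self.standardize is None:
            return _DEFAULT_STANDARDIZE[self.backend]
        return self.standardize


@dataclass
class TrainedModel:
    backend: str
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    config: ModelConfig


def _make_estimator(config: ModelConfig):
    params = config.resolved_hyperparameters()
    if config.backend == "rf":
        return RandomForestClassifier(random_state=config.seed, **params)
    if config.backend == "svm":
        return SVC(random_state=config.seed, **params)
    return MLPClassifier(random_state=config.seed, **params)


def train(matrix: FeatureMatrix, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the configured backend; deterministic given (matrix, config)."""
    config = config or ModelConfig()
    classes = np.unique(matrix.y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isfinite(matrix.X)):
        raise ValueError("training matrix contains non-finite values")

    steps = []
    if config.resolved_standardize():
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_estimator(config)))
    pipeline = Pipeline(steps)
    pipeline.fit(matrix.X, matrix.y)
    return TrainedModel(
        backend=config.backend,
        pipeline=pipeline,
        feature_names=tuple(matrix.names),
        config=config,
    )


def predict(
    model: TrainedModel, matrix: FeatureMatrix, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class-1 scores in [0, 1] on a feature matrix.

    The matrix's feature names must match (same names, same order) the
    names the model was trained on.
    """
    if tuple(matrix.names) != model.feature_names:
        raise ValueError(
            "feature names do not match the model's training layout; "
            "refusing to predict"
        )
    threshold = model.config.threshold if threshold is None else threshold
    scores = _scores(model, matrix.X)
    labels = (scores >= threshold).astype(int)
    return labels, scores


def _scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    clf = model.pipeline
    if model.backend == "svm":
        # SVC without probability calibration: squash the margin into [0, 1]
        return expit(clf.decision_function(X))
    proba = clf.predict_proba(X)
    class_index = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, class_index]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the fitted pipeline plus a JSON sidecar describing it."""
    path = Path(path)
    joblib.dump(model.pipeline, path)
    sidecar = {
        "backend": model.backend,
        "hyperparameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.config.resolved_hyperparameters().items()
        },
        "seed": model.config.seed,
        "standardize": model.config.resolved_standardize(),
        "threshold": model.config.threshold,
        "feature_names": list(model.feature_names),
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model, verifying its sidecar exists and is well-formed."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"model sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("backend", "feature_names", "seed"):
        if key not in sidecar:
            raise ValueError(f"model sidecar is missing field {key!r}")
    hyper = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in sidecar.get("hyperparameters", {}).items()
    }
    config = ModelConfig(
        backend=sidecar["backend"],
        hyperparameters=hyper,
        seed=sidecar["seed"],
        standardize=sidecar.get("standardize"),
        threshold=sidecar.get("threshold", 0.5),
    )
    return TrainedModel(
        backend=sidecar["backend"],
        pipeline=joblib.load(path),
        feature_names=tuple(sidecar["feature_names"]),
        config=config,
    )
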