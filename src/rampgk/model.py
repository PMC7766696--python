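"""Linear C-SVC classifier over flattened adjacency-matrix features.

A thin, schema-aware wrapper around scikit-learn's libsvm-backed ``SVC``.
The decision contract is fixed: ``score(x)`` is the signed distance to
the separating hyperplane and a site is called positive iff its score is
strictly greater than zero (ties go to negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import json
import joblib
import numpy as np
from sklearn.svm import SVC

from .ram import FeatureSchema


@dataclass
class ModelConfig:
    """C-classification SVM settings.

    The kernel is fixed to linear; other kernels are rejected unless
    ``allow_nonlinear`` is set.  ``C`` defaults to 1 (the libsvm
    default).  Optional per-feature standardization is fit on the
    training set only.
    """

    kernel: str = "linear"
    C: float = 1.0
    class_weight: Optional[dict] = None
    standardize: bool = False
    allow_nonlinear: bool = False
    #: libsvm stopping tolerance; tighten (e.g. 1e-7) when score-level
    #: reproducibility under row permutation matters more than fit time
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.kernel != "linear" and not self.allow_nonlinear:
            raise ValueError(
                f"kernel {self.kernel!r} rejected; only 'linear' is "
                "supported without allow_nonlinear"
            )
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature schema it was trained on."""

    clf: SVC
    schema: Optional[FeatureSchema]
    config: ModelConfig
    scale_mean: Optional[np.ndarray] = None
    scale_sd: Optional[np.ndarray] = None
    n_features: int = 0

    def _validate(self, features) -> np.ndarray:
        schema = getattr(features, "schema", None)
        X = np.asarray(getattr(features, "X", features), dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if self.schema is not None and schema is not None and schema != self.schema:
            raise ValueError(
                "feature schema mismatch: model trained under "
                f"{self.schema.to_dict()}, got {schema.to_dict()}"
            )
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_sd
        return X

    def decision_scores(self, features) -> np.ndarray:
        """Signed distance of each row to the separating hyperplane."""
        X = self._validate(features)
        if X.shape[0] == 0:
            return np.array([], dtype=float)
        return np.asarray(self.clf.decision_function(X), dtype=float)

    def predict(self, features) -> np.ndarray:
        """Binary calls: positive iff decision score > 0."""
        return (self.decision_scores(features) > 0).astype(int)

    def save(self, path) -> None:
        path = Path(path)
        joblib.dump(self, path)
        sidecar = path.with_suffix(path.suffix + ".schema.json")
        meta = {
            "schema": self.schema.to_dict() if self.schema else None,
            "n_features": self.n_features,
            "C": self.config.C,
            "kernel": self.config.kernel,
            "standardize": self.config.standardize,
        }
        sidecar.write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path) -> TrainedModel:
    return joblib.load(path)


def train(features, labels, config: Optional[ModelConfig] = None) -> TrainedModel:
    """Fit the linear C-SVC on a feature table (or raw array) and labels."""
    config = config or ModelConfig()
    schema = getattr(features, "schema", None)
    X = np.asarray(getattr(features, "X", features), dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("features and labels length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training set contains a single class: {classes}")

    scale_mean = scale_sd = None
    if config.standardize:
        scale_mean = X.mean(axis=0)
        scale_sd = X.std(axis=0)
        scale_sd = np.where(scale_sd == 0, 1.0, scale_sd)
        X = (X - scale_mean) / scale_sd

    clf = SVC(
        kernel=config.kernel,
        C=config.C,
        class_weight=config.class_weight,
        tol=config.tol,
    )
    clf.fit(X, y)
    return TrainedModel(
        clf=clf,
        schema=schema,
        config=config,
        scale_mean=scale_mean,
        scale_sd=scale_sd,
        n_features=X.shape[1],
    )
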