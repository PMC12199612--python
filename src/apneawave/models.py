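"""Feature-based baseline classifiers: logistic regression, SVM, XGBoost.

These operate on the 8 low-dimensional statistical features and serve as the
comparison point for the transformer. All trainers are deterministic under a
fixed seed and expose calibrated-ish probability outputs.
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["TrainedModel", "train_baseline", "sensitivity_threshold", "save_model", "load_model"]

BASELINE_KINDS = ("lr", "svm", "xgboost")


@dataclass
class TrainedModel:
    """A fitted baseline with its config snapshot and data fingerprint."""

    kind: str
    estimator: object
    feature_names: list[str]
    threshold: float = 0.5
    config: dict = field(default_factory=dict)
    fingerprint: Optional[str] = None

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """P(apnea) per row; a pure function of (model, input)."""
        return self.estimator.predict_proba(self._matrix(X))[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_baseline(features, labels, kind: str = "lr", seed: int = 0) -> TrainedModel:
    """Fit one baseline classifier on a feature table.

    ``features`` may be a DataFrame (a ``label`` column, if present, is
    ignored) or a plain array. Constant feature columns are warned about and
    kept — they carry no information but do not break any of the estimators.

    Raises
    ------
    ValueError
        For an unknown kind or fewer than 2 samples in either class.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns if c != "label"]
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    const = [names[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    if const:
        warnings.warn(f"constant feature column(s): {const}", stacklevel=2)

    if kind == "lr":
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed),
        )
    elif kind == "svm":
        # RBF SVM; Platt-style probability calibration on internal folds
        est = make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=seed), ensemble=False),
        )
    else:
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="logloss",
        )
    est.fit(X, y)
    return TrainedModel(
        kind=kind,
        estimator=est,
        feature_names=names,
        config={"kind": kind, "seed": seed},
        fingerprint=_fingerprint(X, y),
    )


def sensitivity_threshold(scores, labels, target_sensitivity: float = 0.95) -> float:
    """Largest decision threshold whose sensitivity on (scores, labels) meets
    the target; used to set the screening model's operating point from
    validation data. Falls back to just below the lowest positive score if
    even that cannot meet the target (then sensitivity is 1 by construction).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = np.sort(s[y == 1])
    if pos.size == 0:
        raise ValueError("no positive samples to tune a sensitivity threshold on")
    n_miss = int(np.floor((1.0 - target_sensitivity) * pos.size))
    # allowing the lowest n_miss positives to fall below threshold
    return float(pos[n_miss]) if n_miss < pos.size else float(pos[-1])


def save_model(model, path) -> None:
    """Serialize any trained model (baseline or ViT) to a single file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)
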