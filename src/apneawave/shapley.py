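"""Exact Shapley feature attributions for the low-dimensional models.

With only 8 statistical features, the Shapley value can be computed by
exhaustive enumeration of all 2^d feature coalitions under the standard
interventional value function: v(S) is the model output with features in S
taken from the explained sample and the rest marginalized over a background
dataset. Exhaustive enumeration makes the local-accuracy identity

    sum_j phi_j = f(x) - E_background[f]

hold exactly (up to floating point), with no sampling error.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["exact_shapley", "shap_attribution"]

_MAX_FEATURES = 16


def exact_shapley(predict_fn, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature Shapley attributions by coalition enumeration.

    Parameters
    ----------
    predict_fn : callable
        Maps an (n, d) array to (n,) model outputs (e.g. P(apnea)).
    X : (n, d) array
        Samples to explain.
    background : (m, d) array
        Reference dataset the absent features are marginalized over.

    Returns
    -------
    (n, d) array of attributions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = X.shape
    if d > _MAX_FEATURES:
        raise ValueError(f"exhaustive enumeration supports up to {_MAX_FEATURES} features, got {d}")
    m = bg.shape[0]

    # v[mask] : (n,) coalition values, mask = bitmask over features
    v = {}
    for size in range(d + 1):
        for S in combinations(range(d), size):
            mask = sum(1 << j for j in S)
            # rows: for each sample, every background row with S overridden by x
            rows = np.repeat(bg[None, :, :], n, axis=0)  # (n, m, d)
            for j in S:
                rows[:, :, j] = X[:, j][:, None]
            v[mask] = predict_fn(rows.reshape(n * m, d)).reshape(n, m).mean(axis=1)

    phi = np.zeros((n, d))
    fact = [factorial(k) for k in range(d + 1)]
    for j in range(d):
        for size in range(d):
            w = fact[size] * fact[d - size - 1] / fact[d]
            for S in combinations([k for k in range(d) if k != j], size):
                mask = sum(1 << k for k in S)
                phi[:, j] += w * (v[mask | (1 << j)] - v[mask])
    return phi


def shap_attribution(model, features, background=None) -> np.ndarray:
    """Shapley attributions of a trained baseline over its feature table.

    Attribution is defined on the statistical-feature models only; the
    transformer consumes raw waveforms, not the 8-feature table, so it is
    rejected here.

    Parameters
    ----------
    model : TrainedModel
        A fitted lr / svm / xgboost baseline.
    features : DataFrame or array
        Rows to explain.
    background : optional
        Reference rows; defaults to the explained rows themselves.
    """
    if getattr(model, "kind", None) == "vit":
        raise ValueError("Shapley attribution is defined on the feature-based baselines only")
    if isinstance(features, pd.DataFrame):
        X = features[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if background is None:
        bg = X
    elif isinstance(background, pd.DataFrame):
        bg = background[model.feature_names].to_numpy(dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    return exact_shapley(model.predict_proba, X, bg)
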