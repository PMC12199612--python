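"""Repeated stratified 7:2:1 split evaluation.

The evaluation protocol draws ten independent stratified random splits into
training : validation : test = 0.7 : 0.2 : 0.1 with distinct seeds and
reports mean +/- std of accuracy, sensitivity, specificity and AUC over the
repetitions. (A literal k-fold with 7:2:1 fractions is not self-consistent;
repeated random resampling realizes the same train/validate/test protocol.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import confusion_metrics, roc_auc

__all__ = ["SplitPlan", "stratified_split", "evaluate_splits"]


@dataclass(frozen=True)
class SplitPlan:
    """Repetition count, split fractions and seeding of the protocol."""

    n_repetitions: int = 10
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    base_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")

    def seeds(self) -> list[int]:
        return [self.base_seed + r for r in range(self.n_repetitions)]


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer part sizes summing to n, largest-remainder rounding."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # most-deficient first
    for k in range(rem):
        sizes[order[k]] += 1
    return sizes


def stratified_split(
    labels: Sequence[int], fractions: Sequence[float], seed: int, stratified: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint (train, val, test) index arrays covering all samples."""
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    groups = [np.flatnonzero(y == c) for c in np.unique(y)] if stratified else [np.arange(len(y))]
    for idx in groups:
        idx = rng.permutation(idx)
        n_tr, n_va, n_te = _allocate(len(idx), fractions)
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr : n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va :])
    return tuple(np.sort(np.asarray(p)) for p in parts)  # type: ignore[return-value]


def evaluate_splits(
    data: Sequence,
    labels: Sequence[int],
    trainer: Callable,
    plan: SplitPlan = SplitPlan(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the repeated-split protocol with a user-supplied trainer.

    ``trainer(train_data, train_labels, val_data, val_labels, seed)`` must
    return an object with ``predict_proba(data) -> (n,) scores`` and an
    optional ``threshold`` (default 0.5). ``data`` may be a DataFrame, an
    array, or a list of segments; rows are selected by position.

    Returns
    -------
    (per_repetition, aggregate)
        Per-repetition ACC/SEN/SPE/AUC table and its mean/std summary.
    """
    y = np.asarray(labels).astype(int)
    if min(np.bincount(y, minlength=2)) < plan.n_repetitions:
        raise ValueError("dataset too small: need >= n_repetitions samples per class")

    def take(seq, idx):
        if isinstance(seq, pd.DataFrame):
            return seq.iloc[idx]
        if isinstance(seq, np.ndarray):
            return seq[idx]
        return [seq[i] for i in idx]

    rows = []
    for rep, seed in enumerate(plan.seeds()):
        tr, va, te = stratified_split(y, plan.fractions, seed, plan.stratified)
        model = trainer(take(data, tr), y[tr], take(data, va), y[va], seed)
        scores = np.asarray(model.predict_proba(take(data, te)), dtype=float)
        thr = getattr(model, "threshold", 0.5)
        rep_report = confusion_metrics((scores >= thr).astype(int), y[te])
        _, auc = roc_auc(scores, y[te])
        rows.append(
            {
                "repetition": rep,
                "seed": seed,
                "n_train": len(tr),
                "n_val": len(va),
                "n_test": len(te),
                "accuracy": rep_report.accuracy,
                "sensitivity": rep_report.sensitivity,
                "specificity": rep_report.specificity,
                "auc": auc,
            }
        )
    table = pd.DataFrame(rows)
    metrics = ["accuracy", "sensitivity", "specificity", "auc"]
    aggregate = pd.DataFrame({"mean": table[metrics].mean(), "std": table[metrics].std(ddof=0)})
    return table, aggregate
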