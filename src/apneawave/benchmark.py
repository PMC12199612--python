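"""The standard synthetic benchmark: generation, training and evaluation.

One call builds the balanced severity-1 dataset, trains the high-accuracy
configuration (ViT on PPG + SpO2 + hypoxic burden), the PPW-only screening
model with its validation-tuned high-sensitivity threshold, the three
feature baselines, and replays the two-stage cascade on the held-out test
segments. Everything is deterministic in the single seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cascade import replay_cascade
from .datasets import make_benchmark
from .evaluation import stratified_split
from .metrics import confusion_metrics, roc_auc
from .models import sensitivity_threshold, train_baseline
from .preprocess import features_table
from .vit import VitConfig, train_vit

__all__ = ["run_standard_benchmark"]


def run_standard_benchmark(
    n_per_class: int = 500,
    severity: float = 1.0,
    seed: int = 7,
    vit_epochs: int = 10,
    screen_target_sensitivity: float = 0.95,
    include_baselines: bool = True,
    vit_config: Optional[VitConfig] = None,
    screen_config: Optional[VitConfig] = None,
) -> dict:
    """Train and evaluate the full model stack on the standard benchmark.

    Returns a flat dict of metrics: high-accuracy model ACC/SEN/SPE/AUC,
    screening model sensitivity/specificity at its tuned threshold, cascade
    accuracy and stage-2 duty cycle, and (optionally) baseline accuracies.
    """
    segments, labels = make_benchmark(n_per_class=n_per_class, severity=severity, seed=seed)
    tr, va, te = stratified_split(labels, (0.7, 0.2, 0.1), seed=seed)
    seg_tr, seg_va, seg_te = ([segments[i] for i in part] for part in (tr, va, te))
    y_tr, y_va, y_te = labels[tr], labels[va], labels[te]

    # high-accuracy configuration: PPG + SpO2 + hypoxic-burden token
    cfg_hi = vit_config or VitConfig(channels="ppg+spo2+hb", epochs=vit_epochs, seed=seed)
    vit_hi = train_vit(seg_tr, y_tr, seg_va, y_va, cfg_hi)
    p_hi = vit_hi.predict_proba(seg_te)
    rep_hi = confusion_metrics((p_hi >= vit_hi.threshold).astype(int), y_te)
    _, auc_hi = roc_auc(p_hi, y_te)

    # PPW-only screen, operated at a validation-tuned high-sensitivity point
    cfg_ppw = screen_config or VitConfig(channels="ppw", epochs=vit_epochs, seed=seed + 1)
    vit_ppw = train_vit(seg_tr, y_tr, seg_va, y_va, cfg_ppw)
    thr = sensitivity_threshold(
        vit_ppw.predict_proba(seg_va), y_va, target_sensitivity=screen_target_sensitivity
    )
    vit_ppw.threshold = thr
    p_ppw = vit_ppw.predict_proba(seg_te)
    rep_ppw = confusion_metrics((p_ppw >= thr).astype(int), y_te)

    # two-stage cascade, replayed per held-out segment
    preds, duty = replay_cascade(seg_te, p_ppw, p_hi, thr, vit_hi.threshold)
    rep_cascade = confusion_metrics(preds, y_te)

    out = {
        "n_segments": len(segments),
        "n_test": len(seg_te),
        "vit_accuracy": rep_hi.accuracy,
        "vit_sensitivity": rep_hi.sensitivity,
        "vit_specificity": rep_hi.specificity,
        "vit_auc": auc_hi,
        "screen_threshold": thr,
        "screen_sensitivity": rep_ppw.sensitivity,
        "screen_specificity": rep_ppw.specificity,
        "cascade_accuracy": rep_cascade.accuracy,
        "cascade_sensitivity": rep_cascade.sensitivity,
        "cascade_specificity": rep_cascade.specificity,
        "cascade_duty_cycle": duty,
    }

    if include_baselines:
        table = features_table(segments, include_hb=True)
        feats = table.drop(columns=["label"])
        for kind in ("lr", "svm", "xgboost"):
            model = train_baseline(feats.iloc[np.concatenate([tr, va])],
                                   labels[np.concatenate([tr, va])], kind, seed=seed)
            rep = confusion_metrics(model.predict(feats.iloc[te]), y_te)
            out[f"{kind}_accuracy"] = rep.accuracy
    return out
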