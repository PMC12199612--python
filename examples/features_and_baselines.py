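"""Segment a benchmark dataset, extract the 8 statistical features, and
compare the feature baselines under the repeated 7:2:1 protocol.

Prints the per-repetition and aggregate ACC/SEN/SPE/AUC of a logistic
regression on the canonical features (SpO2 and peak-interval mean/max/min/
std), plus exact Shapley attributions showing which features carry the
signal.
"""

import numpy as np

import apneawave as aw

segments, labels = aw.make_benchmark(n_per_class=60, severity=1.0, seed=3)
table = aw.features_table(segments, include_hb=True)
feats = table.drop(columns=["label"])
print(f"{len(table)} segments, features: {list(feats.columns)}")


def trainer(Xtr, ytr, Xva, yva, seed):
    return aw.train_baseline(Xtr, ytr, "lr", seed=seed)


plan = aw.SplitPlan(n_repetitions=10, base_seed=0)
per_rep, aggregate = aw.evaluate_splits(feats, labels, trainer, plan)
print("\nper-repetition metrics:")
print(per_rep[["repetition", "accuracy", "sensitivity", "specificity", "auc"]]
      .to_string(index=False))
print("\naggregate (mean +/- std over 10 repetitions):")
print(aggregate.round(4).to_string())

# Which features drive the decisions? Exact Shapley over the 2^11 coalitions.
model = aw.train_baseline(feats, labels, "lr", seed=0)
phi = aw.shap_attribution(model, feats.iloc[:50], background=feats.iloc[:50])
mean_abs = np.abs(phi).mean(axis=0)
print("\nmean |Shapley value| per feature (probability scale):")
for name, v in sorted(zip(model.feature_names, mean_abs), key=lambda kv: -kv[1]):
    print(f"  {name:16s} {v:.4f}")
# SpO2 depth statistics (min/std) dominate: desaturation is the most direct
# apnea signature; peak-interval spread adds the autonomic component.
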