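"""Transformer, baselines, Shapley attributions and the split protocol."""

import numpy as np
import pandas as pd
import pytest

import apneawave as aw
from apneawave.evaluation import _allocate, stratified_split
from apneawave.shapley import exact_shapley

SMALL_VIT = dict(epochs=3, depth=2, seed=0)


# ---------------------------------------------------------------------------
# patchify
# ---------------------------------------------------------------------------

def test_patchify_counts_and_reconstruction():
    cfg = aw.VitConfig(channels="ppg+spo2", patch_len=32)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(4, 2, cfg.input_len))
    patches = aw.patchify(X, cfg)
    assert patches.shape == (4, cfg.input_len // 32, 2 * 32)
    from apneawave.vit import unpatchify

    assert np.array_equal(unpatchify(patches, cfg, 2), X)


def test_patchify_locality():
    cfg = aw.VitConfig(channels="ppg", patch_len=32)
    rng = np.random.default_rng(1)
    X = rng.normal(size=(1, 1, cfg.input_len))
    Y = X.copy()
    k = 7
    Y[0, 0, k * 32 : (k + 1) * 32] += 1.0
    diff = np.any(aw.patchify(X, cfg) != aw.patchify(Y, cfg), axis=2)[0]
    assert diff[k] and diff.sum() == 1


def test_vit_config_invariants():
    with pytest.raises(ValueError):
        aw.VitConfig(patch_len=33)  # does not divide 3840
    with pytest.raises(ValueError):
        aw.VitConfig(embed_dim=64, heads=5)
    with pytest.raises(ValueError):
        aw.VitConfig(channels="ecg")


# ---------------------------------------------------------------------------
# ViT training
# ---------------------------------------------------------------------------

def _split(labels, seed=0, fractions=(0.7, 0.2, 0.1)):
    return stratified_split(labels, fractions, seed)


def test_vit_deterministic_and_separates(small_benchmark):
    segments, labels = small_benchmark
    tr, va, te = _split(labels)
    cfg = aw.VitConfig(**SMALL_VIT)
    args = ([segments[i] for i in tr], labels[tr], [segments[i] for i in va], labels[va], cfg)
    m1 = aw.train_vit(*args)
    m2 = aw.train_vit(*args)
    test_segs = [segments[i] for i in te]
    p1, p2 = m1.predict_proba(test_segs), m2.predict_proba(test_segs)
    assert np.array_equal(p1, p2)  # bit-identical under the same seed
    assert np.all((p1 >= 0) & (p1 <= 1))
    acc = np.mean((p1 >= 0.5) == (labels[te] == 1))
    assert acc >= 0.9  # severity-1 events are well separated


def test_vit_label_permutation_null(small_benchmark):
    segments, labels = small_benchmark
    rng = np.random.default_rng(123)
    shuffled = rng.permutation(labels)
    tr, va, te = _split(shuffled)
    cfg = aw.VitConfig(**SMALL_VIT)
    m = aw.train_vit([segments[i] for i in tr], shuffled[tr],
                     [segments[i] for i in va], shuffled[va], cfg)
    acc = np.mean(m.predict([segments[i] for i in te]) == shuffled[te])
    assert 0.25 <= acc <= 0.75  # no real signal to learn


def test_vit_single_class_rejected(small_benchmark):
    segments, labels = small_benchmark
    pos = [s for s, l in zip(segments, labels) if l == 1][:10]
    with pytest.raises(ValueError):
        aw.train_vit(pos, [1] * 10, pos, [1] * 10, aw.VitConfig(**SMALL_VIT))


def test_vit_gradients_match_finite_differences():
    """Backprop oracle: analytic gradient of the loss against central finite
    differences on a tiny model."""
    from apneawave.vit import _backward, _forward, _init_params, _sigmoid

    cfg = aw.VitConfig(channels="ppg", common_rate=2.0, window=8.0,
                       patch_len=4, embed_dim=8, depth=1, heads=2, mlp_dim=16, seed=0)
    rng = np.random.default_rng(0)
    patches = rng.normal(size=(3, cfg.n_patches, 4))
    hb = np.zeros(3)
    y = np.array([1.0, 0.0, 1.0])
    params = _init_params(cfg, 4, rng)

    def loss_of(p):
        logits, _ = _forward(p, patches, hb, cfg, want_cache=False)
        return float(np.mean(np.logaddexp(0.0, logits) - y * logits))

    logits, cache = _forward(params, patches, hb, cfg, want_cache=True)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    _backward(params, grads, (_sigmoid(logits) - y) / 3, cache, cfg)

    eps = 1e-6
    for key in ("embed_w", "b0_wqkv", "b0_w1", "head_w", "pos", "cls", "b0_ln1_g"):
        flat_idx = [0, params[key].size // 2, params[key].size - 1]
        for fi in flat_idx:
            p_plus = {k: v.copy() for k, v in params.items()}
            p_minus = {k: v.copy() for k, v in params.items()}
            p_plus[key].flat[fi] += eps
            p_minus[key].flat[fi] -= eps
            num = (loss_of(p_plus) - loss_of(p_minus)) / (2 * eps)
            assert grads[key].flat[fi] == pytest.approx(num, rel=1e-3, abs=1e-7), key


def test_monotone_severity_auc():
    """Stronger simulated events never make the high-accuracy configuration
    less discriminative (up to finite-sample jitter of the AUC estimate)."""
    means = {}
    for sev in (0.3, 0.6, 1.0):
        aucs = []
        for seed in (0, 1, 2):
            segs, labels = aw.make_benchmark(n_per_class=50, severity=sev, seed=100 + seed)
            tr, va, te = stratified_split(labels, (0.6, 0.2, 0.2), seed=seed)
            cfg = aw.VitConfig(epochs=5, depth=2, seed=seed)
            m = aw.train_vit([segs[i] for i in tr], labels[tr],
                             [segs[i] for i in va], labels[va], cfg)
            _, auc = aw.roc_auc(m.predict_proba([segs[i] for i in te]), labels[te])
            aucs.append(auc)
        means[sev] = np.mean(aucs)
    assert means[0.6] >= means[0.3] - 0.01
    assert means[1.0] >= means[0.6] - 0.01


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def test_lr_separable_toy():
    X = np.array([[0.0, 0.0], [0.1, 0.2], [1.0, 1.0], [0.9, 1.1]] * 5)
    y = np.array([0, 0, 1, 1] * 5)
    m = aw.train_baseline(X, y, "lr", seed=0)
    assert np.mean(m.predict(X) == y) == 1.0


def test_lr_duplicated_row_probability_half():
    """Identical feature rows with mixed labels: the logistic fit must sit on
    the fence (closed-form optimum gives P = frequency = 0.5)."""
    X = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
    y = np.array([0, 1] * 5 + [0] * 5 + [1] * 5)
    m = aw.train_baseline(X, y, "lr", seed=0)
    p = m.predict_proba(np.zeros((1, 2)))[0]
    assert p == pytest.approx(0.5, abs=0.05)


def test_baseline_kinds_deterministic(small_features):
    table, labels = small_features
    for kind in ("lr", "svm", "xgboost"):
        m1 = aw.train_baseline(table, labels, kind, seed=3)
        m2 = aw.train_baseline(table, labels, kind, seed=3)
        assert np.array_equal(m1.predict_proba(table), m2.predict_proba(table)), kind


def test_constant_column_warns(small_features):
    table, labels = small_features
    t2 = table.copy()
    t2["flat"] = 1.0
    with pytest.warns(UserWarning, match="flat"):
        m = aw.train_baseline(t2, labels, "lr", seed=0)
    assert m is not None


def test_baseline_needs_both_classes(small_features):
    table, labels = small_features
    with pytest.raises(ValueError):
        aw.train_baseline(table, np.ones_like(labels), "lr", seed=0)


def test_sensitivity_threshold_targets_validation():
    scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.2, 0.3, 0.1])
    labels = np.array([1, 1, 1, 1, 1, 0, 0, 0])
    thr = aw.sensitivity_threshold(scores, labels, target_sensitivity=0.95)
    sens = np.mean(scores[labels == 1] >= thr)
    assert sens >= 0.95
    # a laxer target admits a higher threshold
    assert aw.sensitivity_threshold(scores, labels, 0.8) >= thr


def test_model_save_load_roundtrip(tmp_path, small_features):
    table, labels = small_features
    m = aw.train_baseline(table, labels, "lr", seed=0)
    path = tmp_path / "model.pkl"
    aw.save_model(m, path)
    back = aw.load_model(path)
    assert np.array_equal(back.predict_proba(table), m.predict_proba(table))
    assert back.fingerprint == m.fingerprint


# ---------------------------------------------------------------------------
# Shapley attributions
# ---------------------------------------------------------------------------

def _brute_shapley_2f(predict, x, bg):
    """Independent 2-feature enumeration over the 2^2 coalitions."""
    def v(mask):
        rows = bg.copy()
        for j in (0, 1):
            if mask & (1 << j):
                rows[:, j] = x[j]
        return predict(rows).mean()

    phi0 = 0.5 * (v(0b01) - v(0b00)) + 0.5 * (v(0b11) - v(0b10))
    phi1 = 0.5 * (v(0b10) - v(0b00)) + 0.5 * (v(0b11) - v(0b01))
    return np.array([phi0, phi1])


def test_shapley_matches_exhaustive_enumeration():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 0, 1, 1])
    m = aw.train_baseline(X, y, "lr", seed=0)
    phi = exact_shapley(m.predict_proba, X, X)
    for i in range(4):
        oracle = _brute_shapley_2f(m.predict_proba, X[i], X.copy())
        assert np.allclose(phi[i], oracle, atol=1e-12)


def test_shapley_local_accuracy(small_features):
    table, labels = small_features
    m = aw.train_baseline(table, labels, "xgboost", seed=0)
    X = table[m.feature_names].to_numpy()[:8]
    bg = table[m.feature_names].to_numpy()[:32]
    phi = aw.shap_attribution(m, X, background=bg)
    f = m.predict_proba(X)
    base = m.predict_proba(bg).mean()
    assert np.abs(phi.sum(axis=1) - (f - base)).max() < 1e-6


def test_shapley_ignored_feature_zero_attribution():
    """A feature the model provably ignores gets exactly zero credit."""
    X = np.array([[0.0, 5.0], [1.0, -3.0], [2.0, 8.0], [3.0, 0.0]])

    def predict(rows):
        return 1.0 / (1.0 + np.exp(-(rows[:, 0] - 1.5)))  # uses feature 0 only

    phi = exact_shapley(predict, X, X)
    assert np.all(phi[:, 1] == 0.0)
    assert np.any(phi[:, 0] != 0.0)


def test_shapley_rejects_vit(small_benchmark):
    class FakeVit:
        kind = "vit"

    with pytest.raises(ValueError):
        aw.shap_attribution(FakeVit(), np.zeros((2, 8)))


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

def test_split_sizes_100():
    tr, va, te = stratified_split(np.array([0, 1] * 50), (0.7, 0.2, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (70, 20, 10)
    assert len(set(tr) | set(va) | set(te)) == 100  # disjoint partition


def test_split_stratification_balance():
    y = np.array([0] * 50 + [1] * 50)
    tr, va, te = stratified_split(y, (0.7, 0.2, 0.1), seed=1)
    for part in (tr, va, te):
        counts = np.bincount(y[part], minlength=2)
        assert abs(counts[0] - counts[1]) <= 1


def test_allocate_largest_remainder():
    assert _allocate(10, (0.7, 0.2, 0.1)) == [7, 2, 1]
    assert sum(_allocate(17, (0.7, 0.2, 0.1))) == 17


def test_split_plan_validation():
    with pytest.raises(ValueError):
        aw.SplitPlan(fractions=(0.5, 0.2, 0.2))


def test_evaluate_splits_baseline(small_features):
    table, labels = small_features

    def trainer(Xtr, ytr, Xva, yva, seed):
        return aw.train_baseline(Xtr, ytr, "lr", seed=seed)

    plan = aw.SplitPlan(n_repetitions=3, base_seed=5)
    per_rep, agg = aw.evaluate_splits(table, labels, trainer, plan)
    assert len(per_rep) == 3
    assert per_rep.n_train.eq(112).all() and per_rep.n_test.eq(16).all()
    assert set(agg.index) == {"accuracy", "sensitivity", "specificity", "auc"}
    assert (agg["mean"] > 0.8).all()  # severity-1 features separate well


def test_evaluate_splits_degenerate_plan_zero_std(small_features):
    """All repetitions identical (same seed) -> aggregate std exactly 0."""
    table, labels = small_features

    class FixedPlan(aw.SplitPlan):
        def seeds(self):
            return [7] * self.n_repetitions

    def trainer(Xtr, ytr, Xva, yva, seed):
        return aw.train_baseline(Xtr, ytr, "lr", seed=0)

    _, agg = aw.evaluate_splits(table, labels, trainer,
                                FixedPlan(n_repetitions=3, base_seed=7))
    assert (agg["std"] == 0.0).all()
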