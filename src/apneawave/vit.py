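"""A compact 1-D Vision Transformer for 2-min physiological segments.

The classifier follows the standard ViT recipe adapted to time series: the
multi-rate channels of a segment are resampled onto a common grid, z-scored
with training-set statistics, cut into fixed-length patches that are linearly
projected to token embeddings, augmented with a learnable class token and
positional embeddings (plus, for the high-accuracy configuration, one extra
token encoding the scalar hypoxic-burden estimate), and passed through
pre-norm transformer blocks (multi-head self-attention + GELU MLP). The MLP
head on the class token outputs the apnea probability.

Implemented directly on NumPy with explicit backpropagation and Adam, so
training is deterministic under a fixed seed and fast enough on a single CPU
for the segment sizes this package works with.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.signal

from .preprocess import Segment, segment_hypoxic_burden
from .record import PPG, PPW, SPO2

__all__ = ["VitConfig", "VitModel", "train_vit", "patchify", "segments_to_tensor"]

#: channel sets the model accepts, mapped to (signal channels, use-HB-token)
CHANNEL_SETS = {
    "ppg+spo2+hb": ((PPG, SPO2), True),
    "ppg+spo2": ((PPG, SPO2), False),
    "ppg": ((PPG,), False),
    "ppw": ((PPW,), False),
}


@dataclass(frozen=True)
class VitConfig:
    """Hyperparameters of the 1-D ViT.

    Defaults are sized to train on one CPU core in minutes: a 32 Hz common
    grid over the 120 s window gives 3840 samples/channel; 1 s patches yield
    120 tokens (+ class token, + optional burden token).
    """

    channels: str = "ppg+spo2+hb"
    common_rate: float = 32.0
    window: float = 120.0
    patch_len: int = 32
    embed_dim: int = 64
    depth: int = 3
    heads: int = 4
    mlp_dim: int = 128
    dropout: float = 0.0
    lr: float = 2e-3
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels not in CHANNEL_SETS:
            raise ValueError(f"unknown channel set {self.channels!r}; choose from {list(CHANNEL_SETS)}")
        if self.input_len % self.patch_len != 0:
            raise ValueError(
                f"patch_len {self.patch_len} must divide the input length {self.input_len}"
            )
        if self.embed_dim % self.heads != 0:
            raise ValueError(f"heads {self.heads} must divide embed_dim {self.embed_dim}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def input_len(self) -> int:
        return int(round(self.common_rate * self.window))

    @property
    def n_patches(self) -> int:
        return self.input_len // self.patch_len

    @property
    def signal_channels(self) -> tuple[str, ...]:
        return CHANNEL_SETS[self.channels][0]

    @property
    def use_hb(self) -> bool:
        return CHANNEL_SETS[self.channels][1]


# ---------------------------------------------------------------------------
# input pipeline
# ---------------------------------------------------------------------------

def _resample_to(x: np.ndarray, rate: float, target_rate: float, n_out: int) -> np.ndarray:
    if rate == target_rate:
        y = x
    elif rate > target_rate:
        up, down = (np.round([target_rate, rate]).astype(int))
        g = np.gcd(up, down)
        y = scipy.signal.resample_poly(x, up // g, down // g)
    else:
        # slow channels (SpO2): linear interpolation onto the fine grid
        t_src = np.arange(len(x)) / rate
        t_dst = np.arange(n_out) / target_rate
        y = np.interp(t_dst, t_src, x)
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y[:n_out]


def segments_to_tensor(
    segments: Sequence[Segment], config: VitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into (N, C, L) on the common grid, plus (N,) HB scalars."""
    n_out = config.input_len
    X = np.empty((len(segments), len(config.signal_channels), n_out))
    hb = np.zeros(len(segments))
    for i, seg in enumerate(segments):
        for c, name in enumerate(config.signal_channels):
            if name not in seg.channels:
                raise ValueError(f"segment {i} lacks required channel {name}")
            x = np.asarray(seg.channels[name], dtype=float)
            if x.size == 0:
                raise ValueError(f"segment {i} channel {name} is empty")
            X[i, c] = _resample_to(x, seg.rates[name], config.common_rate, n_out)
        if config.use_hb:
            hb[i] = segment_hypoxic_burden(seg.channels[SPO2], seg.rates[SPO2])
    return X, hb


def patchify(X: np.ndarray, config: VitConfig) -> np.ndarray:
    """(N, C, L) -> (N, P, C * patch_len), temporal order preserved.

    Each patch concatenates the co-temporal slices of all channels, so two
    inputs differing only inside patch k produce patch sequences differing
    only at index k.
    """
    if X.ndim != 3:
        raise ValueError("expected (N, C, L) input")
    n, c, length = X.shape
    if length % config.patch_len != 0:
        raise ValueError(f"length {length} not divisible by patch_len {config.patch_len}")
    p = length // config.patch_len
    # (N, C, P, patch) -> (N, P, C, patch) -> (N, P, C*patch)
    return (
        X.reshape(n, c, p, config.patch_len)
        .transpose(0, 2, 1, 3)
        .reshape(n, p, c * config.patch_len)
    )


def unpatchify(patches: np.ndarray, config: VitConfig, n_channels: int) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    n, p, _ = patches.shape
    return (
        patches.reshape(n, p, n_channels, config.patch_len)
        .transpose(0, 2, 1, 3)
        .reshape(n, n_channels, p * config.patch_len)
    )


# ---------------------------------------------------------------------------
# layers (forward + explicit backward)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5
_GELU_C = float(np.sqrt(2.0 / np.pi))


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


def _gelu_fwd(x):
    u = _GELU_C * (x + 0.044715 * x**3)
    th = np.tanh(u)
    return 0.5 * x * (1.0 + th), (x, th)


def _gelu_bwd(dy, cache):
    x, th = cache
    du = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
    return dy * (0.5 * (1.0 + th) + 0.5 * x * (1.0 - th**2) * du)


def _attention_fwd(x, p, l, heads):
    b_, t, d = x.shape
    dh = d // heads
    qkv = x @ p[f"b{l}_wqkv"] + p[f"b{l}_bqkv"]
    q, k, v = np.split(qkv, 3, axis=-1)
    q = q.reshape(b_, t, heads, dh).transpose(0, 2, 1, 3)
    k = k.reshape(b_, t, heads, dh).transpose(0, 2, 1, 3)
    v = v.reshape(b_, t, heads, dh).transpose(0, 2, 1, 3)
    scale = 1.0 / np.sqrt(dh)
    scores = (q @ k.transpose(0, 1, 3, 2)) * scale
    scores -= scores.max(-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(-1, keepdims=True)
    ctx = attn @ v  # (B, H, T, dh)
    ctx_m = ctx.transpose(0, 2, 1, 3).reshape(b_, t, d)
    out = ctx_m @ p[f"b{l}_wo"] + p[f"b{l}_bo"]
    return out, (x, q, k, v, attn, ctx_m, scale)


def _attention_bwd(dout, cache, p, grads, l, heads):
    x, q, k, v, attn, ctx_m, scale = cache
    b_, t, d = x.shape
    dh = d // heads
    grads[f"b{l}_wo"] += ctx_m.reshape(-1, d).T @ dout.reshape(-1, d)
    grads[f"b{l}_bo"] += dout.sum((0, 1))
    dctx_m = dout @ p[f"b{l}_wo"].T
    dctx = dctx_m.reshape(b_, t, heads, dh).transpose(0, 2, 1, 3)
    dattn = dctx @ v.transpose(0, 1, 3, 2)
    dv = attn.transpose(0, 1, 3, 2) @ dctx
    dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
    dq = (dscores @ k) * scale
    dk = (dscores.transpose(0, 1, 3, 2) @ q) * scale
    dqkv = np.concatenate(
        [a.transpose(0, 2, 1, 3).reshape(b_, t, d) for a in (dq, dk, dv)], axis=-1
    )
    grads[f"b{l}_wqkv"] += x.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
    grads[f"b{l}_bqkv"] += dqkv.sum((0, 1))
    return dqkv @ p[f"b{l}_wqkv"].T


def _init_params(config: VitConfig, patch_dim: int, rng: np.random.Generator) -> dict:
    d = config.embed_dim
    t = config.n_patches + 1 + (1 if config.use_hb else 0)
    std = 0.02
    p = {
        "embed_w": rng.normal(0, std, (patch_dim, d)),
        "embed_b": np.zeros(d),
        "cls": rng.normal(0, std, (1, 1, d)),
        "pos": rng.normal(0, std, (1, t, d)),
        "lnf_g": np.ones(d),
        "lnf_b": np.zeros(d),
        "head_w": rng.normal(0, std, (d, 1)),
        "head_b": np.zeros(1),
    }
    if config.use_hb:
        p["hb_w"] = rng.normal(0, std, (d,))
        p["hb_b"] = np.zeros(d)
    for l in range(config.depth):
        p[f"b{l}_ln1_g"] = np.ones(d)
        p[f"b{l}_ln1_b"] = np.zeros(d)
        p[f"b{l}_wqkv"] = rng.normal(0, std, (d, 3 * d))
        p[f"b{l}_bqkv"] = np.zeros(3 * d)
        p[f"b{l}_wo"] = rng.normal(0, std, (d, d))
        p[f"b{l}_bo"] = np.zeros(d)
        p[f"b{l}_ln2_g"] = np.ones(d)
        p[f"b{l}_ln2_b"] = np.zeros(d)
        p[f"b{l}_w1"] = rng.normal(0, std, (d, config.mlp_dim))
        p[f"b{l}_b1"] = np.zeros(config.mlp_dim)
        p[f"b{l}_w2"] = rng.normal(0, std, (config.mlp_dim, d))
        p[f"b{l}_b2"] = np.zeros(d)
    return p


def _forward(params, patches, hb, config: VitConfig, want_cache: bool, drop_rng=None):
    n = patches.shape[0]
    d = config.embed_dim
    tok = patches @ params["embed_w"] + params["embed_b"]
    parts = [np.broadcast_to(params["cls"], (n, 1, d)), tok]
    if config.use_hb:
        hb_tok = hb[:, None] * params["hb_w"][None, :] + params["hb_b"]
        parts.append(hb_tok[:, None, :])
    x = np.concatenate(parts, axis=1) + params["pos"]
    caches = []
    keep = 1.0 - config.dropout
    for l in range(config.depth):
        h, c_ln1 = _layernorm_fwd(x, params[f"b{l}_ln1_g"], params[f"b{l}_ln1_b"])
        a, c_att = _attention_fwd(h, params, l, config.heads)
        x1 = x + a
        h2, c_ln2 = _layernorm_fwd(x1, params[f"b{l}_ln2_g"], params[f"b{l}_ln2_b"])
        z1 = h2 @ params[f"b{l}_w1"] + params[f"b{l}_b1"]
        g1, c_gelu = _gelu_fwd(z1)
        if drop_rng is not None and config.dropout > 0:
            mask = (drop_rng.random(g1.shape) < keep) / keep  # inverted dropout
            g1 = g1 * mask
        else:
            mask = None
        m = g1 @ params[f"b{l}_w2"] + params[f"b{l}_b2"]
        x = x1 + m
        if want_cache:
            caches.append((c_ln1, c_att, x1, c_ln2, h2, c_gelu, g1, mask))
    xf, c_lnf = _layernorm_fwd(x, params["lnf_g"], params["lnf_b"])
    cls = xf[:, 0, :]
    logits = (cls @ params["head_w"] + params["head_b"])[:, 0]
    cache = (patches, hb, caches, c_lnf, xf, cls) if want_cache else None
    return logits, cache


def _backward(params, grads, dlogits, cache, config: VitConfig):
    patches, hb, caches, c_lnf, xf, cls = cache
    n = patches.shape[0]
    d = config.embed_dim
    grads["head_w"] += cls.T @ dlogits[:, None]
    grads["head_b"] += dlogits.sum(keepdims=True)
    dxf = np.zeros_like(xf)
    dxf[:, 0, :] = dlogits[:, None] * params["head_w"][:, 0][None, :]
    dx, dg, db = _layernorm_bwd(dxf, c_lnf)
    grads["lnf_g"] += dg
    grads["lnf_b"] += db
    for l in reversed(range(config.depth)):
        c_ln1, c_att, x1, c_ln2, h2, c_gelu, g1, mask = caches[l]
        # MLP branch
        dm = dx
        grads[f"b{l}_w2"] += g1.reshape(-1, config.mlp_dim).T @ dm.reshape(-1, d)
        grads[f"b{l}_b2"] += dm.sum((0, 1))
        dg1 = dm @ params[f"b{l}_w2"].T
        if mask is not None:
            dg1 = dg1 * mask
        dz1 = _gelu_bwd(dg1, c_gelu)
        grads[f"b{l}_w1"] += h2.reshape(-1, d).T @ dz1.reshape(-1, config.mlp_dim)
        grads[f"b{l}_b1"] += dz1.sum((0, 1))
        dh2 = dz1 @ params[f"b{l}_w1"].T
        dx1_ln, dg_, db_ = _layernorm_bwd(dh2, c_ln2)
        grads[f"b{l}_ln2_g"] += dg_
        grads[f"b{l}_ln2_b"] += db_
        dx1 = dx + dx1_ln
        # attention branch
        da = dx1
        dh = _attention_bwd(da, c_att, params, grads, l, config.heads)
        dx_ln, dg_, db_ = _layernorm_bwd(dh, c_ln1)
        grads[f"b{l}_ln1_g"] += dg_
        grads[f"b{l}_ln1_b"] += db_
        dx = dx1 + dx_ln
    grads["pos"] += dx.sum(0, keepdims=True)
    grads["cls"] += dx[:, :1, :].sum(0, keepdims=True)
    dtok = dx[:, 1 : 1 + config.n_patches, :]
    if config.use_hb:
        dhb_tok = dx[:, -1, :]
        grads["hb_w"] += (dhb_tok * hb[:, None]).sum(0)
        grads["hb_b"] += dhb_tok.sum(0)
    grads["embed_w"] += patches.reshape(-1, patches.shape[-1]).T @ dtok.reshape(-1, d)
    grads["embed_b"] += dtok.sum((0, 1))


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# model wrapper and trainer
# ---------------------------------------------------------------------------

@dataclass
class VitModel:
    """A trained ViT: parameters, normalization statistics and config."""

    config: VitConfig
    params: dict
    norm_mean: np.ndarray  # (C,) per-channel mean on the common grid
    norm_std: np.ndarray
    hb_mean: float = 0.0
    hb_std: float = 1.0
    threshold: float = 0.5
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss, val_acc)

    kind: str = "vit"

    def _prepare(self, segments: Sequence[Segment]) -> tuple[np.ndarray, np.ndarray]:
        X, hb = segments_to_tensor(segments, self.config)
        X = (X - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]
        hb = (hb - self.hb_mean) / self.hb_std
        return patchify(X, self.config), hb

    def predict_proba(self, segments: Sequence[Segment], batch_size: int = 64) -> np.ndarray:
        patches, hb = self._prepare(segments)
        out = np.empty(len(patches))
        for i in range(0, len(patches), batch_size):
            logits, _ = _forward(
                self.params, patches[i : i + batch_size], hb[i : i + batch_size],
                self.config, want_cache=False,
            )
            out[i : i + batch_size] = _sigmoid(logits)
        return out

    def predict(self, segments: Sequence[Segment]) -> np.ndarray:
        return (self.predict_proba(segments) >= self.threshold).astype(int)


def train_vit(
    train_segments: Sequence[Segment],
    train_labels: Sequence[int],
    val_segments: Sequence[Segment],
    val_labels: Sequence[int],
    config: Optional[VitConfig] = None,
) -> VitModel:
    """Train the 1-D ViT; returns the weights of the best-validation epoch.

    Deterministic under a fixed ``config.seed``. Raises ``ValueError`` if the
    training set contains a single class.
    """
    config = config or VitConfig()
    y = np.asarray(train_labels, dtype=float)
    yv = np.asarray(val_labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    X, hb = segments_to_tensor(train_segments, config)
    norm_mean = X.mean(axis=(0, 2))
    norm_std = np.maximum(X.std(axis=(0, 2)), 1e-8)
    hb_mean, hb_std = float(hb.mean()), float(max(hb.std(), 1e-8))
    X = (X - norm_mean[None, :, None]) / norm_std[None, :, None]
    hb = (hb - hb_mean) / hb_std
    patches = patchify(X, config)

    model = VitModel(
        config=config, params={}, norm_mean=norm_mean, norm_std=norm_std,
        hb_mean=hb_mean, hb_std=hb_std,
    )
    Xv, hbv = segments_to_tensor(val_segments, config)
    Xv = (Xv - norm_mean[None, :, None]) / norm_std[None, :, None]
    hbv = (hbv - hb_mean) / hb_std
    patches_v = patchify(Xv, config)

    rng = np.random.default_rng(config.seed)
    params = _init_params(config, patches.shape[-1], rng)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def val_metrics() -> tuple[float, float]:
        logits, _ = _forward(params, patches_v, hbv, config, want_cache=False)
        p = _sigmoid(logits)
        loss = float(np.mean(-(yv * np.log(p + 1e-12) + (1 - yv) * np.log(1 - p + 1e-12))))
        acc = float(np.mean((p >= 0.5) == (yv == 1)))
        return loss, acc

    best = (np.inf, None)
    n = len(patches)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, hbb, yb = patches[idx], hb[idx], y[idx]
            logits, cache = _forward(
                params, xb, hbb, config, want_cache=True,
                drop_rng=rng if config.dropout > 0 else None,
            )
            p = _sigmoid(logits)
            total += float(
                np.sum(np.logaddexp(0.0, logits) - yb * logits)
            )
            dlogits = (p - yb) / len(idx)
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            _backward(params, grads, dlogits, cache, config)
            step += 1
            corr = np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in params:
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= config.lr * corr * m_state[k] / (np.sqrt(v_state[k]) + eps)
        vloss, vacc = val_metrics()
        model.history.append((epoch, total / n, vloss, vacc))
        if vloss < best[0]:
            best = (vloss, copy.deepcopy(params))

    model.params = best[1] if best[1] is not None else params
    return model
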