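"""Segmentation and feature extraction for 2-min analysis windows.

Recordings are cut into consecutive non-overlapping 120 s windows; a window
is labeled apnea-containing when a ground-truth event overlaps it by at least
a configurable minimum (5 s by default). Windows with any contiguous invalid
span longer than 20 s on any channel are excluded, matching standard PSG
quality control.

The low-dimensional feature set is the 8 canonical statistics — mean, max,
min and population std of the SpO2 trace and of the pulse peak-to-peak
interval series — optionally extended with SDNN, the LF/HF spectral ratio of
the interval series, and a per-segment hypoxic-burden estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .record import PPG, PPW, SPO2, ApneaEvent, WaveformRecord

__all__ = [
    "Segment",
    "FeatureVector",
    "InsufficientDataError",
    "segment_record",
    "reject_invalid",
    "detect_peaks",
    "interval_stats",
    "prv_metrics",
    "stft_spectrogram",
    "hypoxic_burden",
    "estimate_desat_onset",
    "segment_hypoxic_burden",
    "extract_features",
    "features_table",
    "FEATURE_NAMES",
]

#: canonical order of the 8 low-dimensional statistical features
FEATURE_NAMES = [
    "spo2_mean", "spo2_max", "spo2_min", "spo2_std",
    "ibi_mean", "ibi_max", "ibi_min", "ibi_std",
]


class InsufficientDataError(ValueError):
    """Raised when a statistic needs more samples than are available."""


@dataclass
class Segment:
    """One labeled 2-min analysis window."""

    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    start: float
    label: bool  # True = apnea-containing
    validity: Optional[dict[str, np.ndarray]] = None
    source_id: str = "record"
    window: float = 120.0
    events: list[ApneaEvent] = field(default_factory=list)  # overlapping ground truth

    def times(self, channel: str) -> np.ndarray:
        return self.start + np.arange(len(self.channels[channel])) / self.rates[channel]


def segment_record(
    record: WaveformRecord,
    window: float = 120.0,
    labeling_overlap: float = 5.0,
) -> list[Segment]:
    """Cut a record into floor(duration/window) consecutive labeled segments.

    A segment is labeled apnea-containing iff some ground-truth event overlaps
    its window by at least ``labeling_overlap`` seconds.
    """
    n_seg = int(record.duration // window)
    if n_seg == 0:
        warnings.warn(
            f"record of {record.duration:.0f} s is shorter than one {window:.0f} s window",
            stacklevel=2,
        )
        return []
    segments = []
    for k in range(n_seg):
        start, stop = k * window, (k + 1) * window
        chans = {}
        valid = {} if record.validity is not None else None
        for name, x in record.channels.items():
            r = record.rates[name]
            i0, i1 = int(round(start * r)), int(round(stop * r))
            chans[name] = x[i0:i1]
            if valid is not None and name in record.validity:
                valid[name] = record.validity[name][i0:i1]
        overlapping = [ev for ev in record.events if ev.overlap(start, stop) > 0]
        label = any(ev.overlap(start, stop) >= labeling_overlap for ev in record.events)
        segments.append(
            Segment(
                channels=chans,
                rates=dict(record.rates),
                start=start,
                label=label,
                validity=valid,
                source_id=record.record_id,
                window=window,
                events=overlapping,
            )
        )
    return segments


def _max_invalid_run(valid: np.ndarray, rate: float) -> float:
    """Longest contiguous invalid (False) run, in seconds."""
    if valid.all():
        return 0.0
    padded = np.concatenate(([True], valid, [True]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = edges[1::2] - edges[0::2]
    return float(runs.max()) / rate


def reject_invalid(segment: Segment, max_invalid_span: float = 20.0) -> bool:
    """True = keep. Drops the segment iff any single contiguous invalid span
    on any channel exceeds ``max_invalid_span`` seconds (disjoint shorter
    dropouts do not accumulate)."""
    if segment.validity is None:
        return True
    for name, valid in segment.validity.items():
        if _max_invalid_run(np.asarray(valid, dtype=bool), segment.rates[name]) > max_invalid_span:
            return False
    return True


def detect_peaks(
    samples: np.ndarray,
    rate: float,
    min_distance: float = 0.33,
    threshold_quantile: float = 0.60,
    refine: bool = True,
) -> np.ndarray:
    """Systolic-peak times (s) via prominence-thresholded local maxima.

    The adaptive threshold is a quantile of the windowed signal plus a
    prominence floor derived from the inner 5-95 % amplitude range, so the
    detector survives the in-event amplitude suppression without locking onto
    noise. A constant signal yields no peaks. The 0.33 s refractory default
    supports heart rates up to ~180 bpm.

    With ``refine`` (default) each peak position gets a parabolic sub-sample
    correction from its two neighbours — essential for interval series from
    the slow 50 Hz channel, where raw grid quantization (20 ms) would
    otherwise dominate the beat-to-beat variability.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if min_distance <= 0:
        raise ValueError("min_distance must be > 0")
    x = np.asarray(samples, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return np.empty(0)
    lo, hi = np.quantile(x, [0.05, 0.95])
    prominence = 0.20 * (hi - lo)
    height = np.quantile(x, threshold_quantile)
    idx, _ = scipy.signal.find_peaks(
        x, distance=max(1, int(round(min_distance * rate))),
        height=height, prominence=prominence,
    )
    pos = idx.astype(float)
    if refine and idx.size:
        inner = (idx > 0) & (idx < x.size - 1)
        i = idx[inner]
        denom = x[i - 1] - 2 * x[i] + x[i + 1]
        ok = denom < 0
        shift = np.zeros(i.size)
        shift[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
        pos[inner] += np.clip(shift, -0.5, 0.5)
    return pos / rate


def interval_stats(peak_times: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, max, min, population std) of successive peak-to-peak intervals.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 peaks (i.e. fewer than 2 intervals).
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 3:
        raise InsufficientDataError(f"need >= 3 peaks for interval statistics, got {t.size}")
    d = np.diff(t)
    return float(d.mean()), float(d.max()), float(d.min()), float(d.std(ddof=0))


def prv_metrics(
    peak_times: np.ndarray,
    lf_band: tuple[float, float] = (0.04, 0.15),
    hf_band: tuple[float, float] = (0.15, 0.40),
    resample_rate: float = 4.0,
) -> tuple[float, float]:
    """Pulse-rate-variability summary: (SDNN in s, LF/HF band-power ratio).

    SDNN is the population std of the inter-beat intervals. For the spectral
    ratio the irregular interval series is linearly resampled onto an even
    ``resample_rate`` grid, mean-removed, and a periodogram integrated over
    the standard LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands.
    """
    t = np.asarray(peak_times, dtype=float)
    if t.size < 4 or (t[-1] - t[1]) < 30.0:
        raise InsufficientDataError("need >= 30 s of inter-beat intervals for a spectral estimate")
    ibi = np.diff(t)
    sdnn = float(ibi.std(ddof=0))
    # interval value attributed to the time of the closing beat
    grid = np.arange(t[1], t[-1], 1.0 / resample_rate)
    even = np.interp(grid, t[1:], ibi)
    even = even - even.mean()
    freqs, psd = scipy.signal.periodogram(even, fs=resample_rate, detrend=False)
    lf = float(np.trapezoid(psd[(freqs >= lf_band[0]) & (freqs < lf_band[1])],
                            freqs[(freqs >= lf_band[0]) & (freqs < lf_band[1])]))
    hf = float(np.trapezoid(psd[(freqs >= hf_band[0]) & (freqs < hf_band[1])],
                            freqs[(freqs >= hf_band[0]) & (freqs < hf_band[1])]))
    ratio = lf / hf if hf > 0 else np.inf
    return sdnn, float(ratio)


def stft_spectrogram(
    samples: np.ndarray,
    rate: float,
    window_len: int,
    hop: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude on Hann-windowed frames.

    Returns ``(freqs, frame_times, magnitude)`` with ``magnitude`` of shape
    (n_freqs, n_frames); frames are fully contained in the signal (no edge
    padding), so ``n_frames = 1 + (n - window_len) // hop``.
    """
    x = np.asarray(samples, dtype=float)
    if window_len > x.size:
        raise ValueError(f"window_len {window_len} exceeds signal length {x.size}")
    if hop <= 0:
        raise ValueError("hop must be > 0")
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop]
    win = scipy.signal.windows.hann(window_len, sym=False)
    mag = np.abs(scipy.fft.rfft(frames * win, axis=1)).T
    freqs = scipy.fft.rfftfreq(window_len, d=1.0 / rate)
    frame_times = (np.arange(frames.shape[0]) * hop + window_len / 2) / rate
    return freqs, frame_times, mag


def hypoxic_burden(
    spo2: np.ndarray,
    rate: float,
    events: Sequence[ApneaEvent],
    total_hours: Optional[float] = None,
    baseline_window: float = 60.0,
    search_after: float = 30.0,
) -> float:
    """Event-associated hypoxic burden, in %·min per hour of recording.

    For each event the pre-event baseline is the mean SpO2 over the
    ``baseline_window`` seconds before onset; the burden is the area of the
    trace below that baseline from onset until ``search_after`` seconds past
    the event end, summed over events and normalized by recording hours.
    """
    x = np.asarray(spo2, dtype=float)
    hours = total_hours if total_hours is not None else len(x) / rate / 3600.0
    if hours <= 0:
        raise ValueError("total duration must be positive")
    area = 0.0  # %·s
    for ev in events:
        if ev.end > len(x) / rate + 1e-9:
            raise ValueError(f"event ending at {ev.end:.1f} s lies outside the trace")
        i1 = int(round(ev.onset * rate))
        i0 = max(0, i1 - int(round(baseline_window * rate)))
        baseline = float(np.mean(x[i0:i1])) if i1 > i0 else float(x[0])
        j1 = min(len(x), int(round((ev.end + search_after) * rate)))
        below = np.clip(baseline - x[i1:j1], 0.0, None)
        area += float(below.sum()) / rate
    return area / 60.0 / hours


def estimate_desat_onset(
    spo2: np.ndarray,
    rate: float,
    search_start: float,
    search_stop: float,
    baseline_window: float = 30.0,
    min_depth: float = 0.5,
    max_depth: float = 8.0,
) -> float:
    """Estimate when a desaturation began, from the trace alone.

    Fits a least-squares line to the early (approximately linear) part of the
    decline — samples whose depth below the pre-window baseline lies in
    [min_depth, max_depth] — and extrapolates back to depth zero. Robust to
    the 1 Hz oximeter grid even for steep declines, where simple two-point
    threshold crossings can collapse onto one sample.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 samples fall on the early decline.
    """
    x = np.asarray(spo2, dtype=float)
    t = np.arange(len(x)) / rate
    base_mask = (t >= search_start - baseline_window) & (t < search_start)
    baseline = float(np.mean(x[base_mask])) if base_mask.any() else float(x[0])
    depth = baseline - x
    window = (t > search_start) & (t <= search_stop)
    # keep only the falling limb: nothing past the nadir of the window
    w_idx = np.flatnonzero(window)
    t_nadir = t[w_idx[np.argmin(x[w_idx])]]
    sel = window & (t <= t_nadir) & (depth >= min_depth) & (depth <= max_depth)
    idx = np.flatnonzero(sel)
    if idx.size < 2:
        raise InsufficientDataError("not enough samples on the decline to fit an onset")
    slope, intercept = np.polyfit(t[idx], depth[idx], 1)
    if slope <= 0:
        raise InsufficientDataError("no declining trend found in the search window")
    return float(-intercept / slope)


def segment_hypoxic_burden(
    spo2: np.ndarray, rate: float, baseline_quantile: float = 0.90
) -> float:
    """Annotation-free per-segment burden (%·min/h): area of the trace below
    its own upper-quantile baseline, normalized by the segment duration."""
    x = np.asarray(spo2, dtype=float)
    if x.size == 0:
        return 0.0
    baseline = float(np.quantile(x, baseline_quantile))
    area = float(np.clip(baseline - x, 0.0, None).sum()) / rate  # %·s
    hours = len(x) / rate / 3600.0
    return area / 60.0 / hours


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 8 canonical statistics plus optional PRV / burden extras."""

    spo2_mean: float
    spo2_max: float
    spo2_min: float
    spo2_std: float
    ibi_mean: float
    ibi_max: float
    ibi_min: float
    ibi_std: float
    sdnn: Optional[float] = None
    lf_hf_ratio: Optional[float] = None
    hypoxic_burden: Optional[float] = None

    def __post_init__(self) -> None:
        for pre in ("spo2", "ibi"):
            lo = getattr(self, f"{pre}_min")
            mu = getattr(self, f"{pre}_mean")
            hi = getattr(self, f"{pre}_max")
            if not (lo <= mu <= hi):
                raise ValueError(f"{pre}: min <= mean <= max violated ({lo}, {mu}, {hi})")
            if getattr(self, f"{pre}_std") < 0:
                raise ValueError(f"{pre}_std must be >= 0")
        if self.lf_hf_ratio is not None and self.lf_hf_ratio < 0:
            raise ValueError("lf_hf_ratio must be >= 0")

    def to_dict(self, extras: bool = False) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        if extras:
            for name in ("sdnn", "lf_hf_ratio", "hypoxic_burden"):
                v = getattr(self, name)
                if v is not None:
                    d[name] = v
        return d


def extract_features(
    segment: Segment,
    pulse_channel: str = PPG,
    include_prv: bool = False,
    include_hb: bool = False,
) -> FeatureVector:
    """Compute the feature vector of one segment.

    Peak-to-peak intervals come from the requested pulse channel; SpO2
    statistics from the oximetry trace. Optional extras add SDNN, the LF/HF
    ratio and the annotation-free hypoxic-burden estimate.
    """
    spo2 = segment.channels[SPO2]
    peaks = detect_peaks(segment.channels[pulse_channel], segment.rates[pulse_channel])
    mean_i, max_i, min_i, std_i = interval_stats(peaks)
    kwargs = {}
    if include_prv:
        sdnn, lf_hf = prv_metrics(peaks)
        kwargs.update(sdnn=sdnn, lf_hf_ratio=lf_hf)
    if include_hb:
        kwargs["hypoxic_burden"] = segment_hypoxic_burden(spo2, segment.rates[SPO2])
    return FeatureVector(
        spo2_mean=float(spo2.mean()),
        spo2_max=float(spo2.max()),
        spo2_min=float(spo2.min()),
        spo2_std=float(spo2.std(ddof=0)),
        ibi_mean=mean_i,
        ibi_max=max_i,
        ibi_min=min_i,
        ibi_std=std_i,
        **kwargs,
    )


def features_table(
    segments: Sequence[Segment],
    pulse_channel: str = PPG,
    include_prv: bool = False,
    include_hb: bool = False,
) -> pd.DataFrame:
    """Feature matrix for a list of segments, one row per segment, with a
    ``label`` column (1 = apnea-containing)."""
    rows = []
    for seg in segments:
        fv = extract_features(seg, pulse_channel, include_prv, include_hb)
        row = fv.to_dict(extras=True)
        row["label"] = int(seg.label)
        rows.append(row)
    return pd.DataFrame(rows)
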