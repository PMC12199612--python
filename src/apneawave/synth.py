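"""Seeded simulator of dual-modal wrist recordings with injectable apnea events.

The generator emulates what a wrist-worn piezoelectric (PPW) + optical
(PPG/SpO2) sensor pair records during sleep:

* a shared cardiac clock (60-100 bpm with configurable pulse-rate
  variability, including respiratory sinus modulation on a 3-5 s breathing
  cycle) drives both pulse channels, so their beat-to-beat interval series
  agree by construction;
* each beat is rendered from a parametric morphology — a sum of Gaussian
  components for the systolic (main) wave, the tidal wave and the dicrotic
  wave, with an optional exponential end-diastolic decay term — which makes
  feature-point positions and amplitude ratios analytically checkable;
* SpO2 rides at a stable 95-99 % baseline with < 2 % variation in the
  absence of events;
* an apnea event suppresses the PPW pulse amplitude by more than half and
  the PPG amplitude by 30-50 %, triggers a delayed (10-20 s) monotone SpO2
  desaturation that can dip below 90 % when severe, and is followed by a
  bounded compensatory amplitude overshoot before the signals return to
  baseline. Outside event + recovery windows the modulation is exactly the
  identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .record import (
    DEFAULT_RATES,
    PPG,
    PPW,
    SPO2,
    ApneaEvent,
    WaveformRecord,
    validate_events,
)

__all__ = [
    "BeatComponent",
    "BeatMorphology",
    "SubjectProfile",
    "SchedulingError",
    "default_morphology",
    "render_beat",
    "beat_value",
    "schedule_events",
    "simulate_subject",
    "apply_apnea_modulation",
]


# ---------------------------------------------------------------------------
# beat morphology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeatComponent:
    """One Gaussian pulse-contour component.

    ``center`` and ``width`` are fractions of the beat period; ``amp`` is in
    arbitrary sensor units (the systolic component conventionally has amp 1).
    """

    amp: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.amp < 0:
            raise ValueError(f"component amplitude must be >= 0, got {self.amp}")
        if not 0.0 <= self.center < 1.0:
            raise ValueError(f"component center must lie in [0, 1), got {self.center}")
        if self.width <= 0:
            raise ValueError(f"component width must be > 0, got {self.width}")


@dataclass(frozen=True)
class BeatMorphology:
    """Parametric single-beat pulse contour.

    The contour is the sum of Gaussian components (systolic first, then the
    later tidal / dicrotic waves in order of their centers) plus an optional
    exponential end-diastolic decay ``decay_amp * exp(-phase / decay_tau)``.
    The systolic component must be strictly the largest, which pins the
    global maximum of the rendered beat to the main wave.
    """

    kind: str  # "PPW" | "PPG"
    components: tuple[BeatComponent, ...]
    decay_amp: float = 0.0
    decay_tau: float = 0.12

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("morphology needs at least the systolic component")
        amps = [c.amp for c in self.components]
        if any(a > 0 for a in amps[1:]) and amps[0] <= max(amps[1:]):
            raise ValueError("systolic (first) component amplitude must be strictly greatest")
        centers = [c.center for c in self.components]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("component centers must be strictly increasing within the beat")
        if self.decay_amp < 0 or self.decay_tau <= 0:
            raise ValueError("decay_amp must be >= 0 and decay_tau > 0")

    @property
    def systolic(self) -> BeatComponent:
        return self.components[0]


def default_morphology(kind: str) -> BeatMorphology:
    """Literature-shaped default contours for each channel.

    The PPG contour carries the classic main wave, tidal wave and dicrotic
    wave of the finger/wrist photoplethysmogram; the piezoelectric PPW
    contour is sharper (the nanogenerator responds to wall acceleration
    rather than blood volume) with an earlier systolic peak.
    """
    if kind == PPG:
        comps = (
            BeatComponent(1.00, 0.17, 0.055),
            BeatComponent(0.38, 0.34, 0.070),
            BeatComponent(0.28, 0.52, 0.060),
        )
        return BeatMorphology(kind=PPG, components=comps)
    if kind == PPW:
        comps = (
            BeatComponent(1.00, 0.13, 0.038),
            BeatComponent(0.45, 0.29, 0.060),
            BeatComponent(0.30, 0.47, 0.050),
        )
        return BeatMorphology(kind=PPW, components=comps)
    raise ValueError(f"unknown channel kind {kind!r}")


def beat_value(morphology: BeatMorphology, phase: np.ndarray) -> np.ndarray:
    """Evaluate the analytic beat contour at ``phase`` (fraction of period).

    Vectorized over arbitrary phase arrays; phases outside [0, 1) are valid
    inputs (the Gaussian tails simply decay), which lets a whole record be
    rendered in one call.
    """
    phase = np.asarray(phase, dtype=float)
    y = np.zeros_like(phase)
    for c in morphology.components:
        y += c.amp * np.exp(-0.5 * ((phase - c.center) / c.width) ** 2)
    if morphology.decay_amp > 0:
        y += morphology.decay_amp * np.exp(-np.clip(phase, 0.0, None) / morphology.decay_tau)
    return y


def render_beat(morphology: BeatMorphology, period: float, rate: float) -> np.ndarray:
    """Render one beat of ``round(period * rate)`` samples.

    Raises
    ------
    ValueError
        If period or rate is not strictly positive.
    """
    if period <= 0:
        raise ValueError(f"beat period must be > 0 s, got {period}")
    if rate <= 0:
        raise ValueError(f"sampling rate must be > 0 Hz, got {rate}")
    n = int(round(period * rate))
    t = np.arange(n) / rate
    return beat_value(morphology, t / period)


# ---------------------------------------------------------------------------
# subject profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Physiological parameters of one simulated sleeper.

    All ranges reflect normal sleep physiology; construction fails outside
    them.

    Parameters
    ----------
    hr_bpm : float
        Mean heart rate, 60-100 bpm.
    hrv_scale : float
        Dimensionless pulse-rate-variability scale (0 = metronomic heart).
    spo2_baseline : float
        Baseline saturation, 95-99 %.
    spo2_noise : float
        Std (%) of the slow baseline SpO2 wander; must keep peak-to-trough
        variation under 2 percentage points.
    resp_period : float
        Breathing-cycle period, 3-5 s; drives respiratory sinus arrhythmia
        and baseline wander of the pulse channels.
    ppw_noise, ppg_noise : float
        White-noise std of each pulse channel, as a fraction of the systolic
        amplitude.
    resp_amp_mod : float
        Fractional beat-amplitude modulation at the breathing frequency.
    morphologies : dict
        Per-channel :class:`BeatMorphology`; defaults per channel kind.
    """

    hr_bpm: float = 72.0
    hrv_scale: float = 0.03
    spo2_baseline: float = 97.0
    spo2_noise: float = 0.15
    resp_period: float = 4.0
    ppw_noise: float = 0.02
    ppg_noise: float = 0.02
    resp_amp_mod: float = 0.05
    morphologies: dict = field(
        default_factory=lambda: {PPW: default_morphology(PPW), PPG: default_morphology(PPG)}
    )

    def __post_init__(self) -> None:
        if not 60.0 <= self.hr_bpm <= 100.0:
            raise ValueError(f"hr_bpm must lie in [60, 100], got {self.hr_bpm}")
        if self.hrv_scale < 0:
            raise ValueError("hrv_scale must be >= 0")
        if not 95.0 <= self.spo2_baseline <= 99.0:
            raise ValueError(f"spo2_baseline must lie in [95, 99], got {self.spo2_baseline}")
        if not 0.0 <= self.spo2_noise <= 0.5:
            raise ValueError("spo2_noise must lie in [0, 0.5] % to keep variation < 2 %")
        if not 3.0 <= self.resp_period <= 5.0:
            raise ValueError(f"resp_period must lie in [3, 5] s, got {self.resp_period}")
        for name in ("ppw_noise", "ppg_noise", "resp_amp_mod"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# event scheduling
# ---------------------------------------------------------------------------

class SchedulingError(ValueError):
    """Raised when the requested events cannot be placed in the record."""


def _nadir_for(severity: float, baseline: float) -> float:
    # depth grows with severity; a severe event (>= 0.7) always dips below 90 %
    return baseline - (3.0 + 9.0 * severity)


def schedule_events(
    ahi: float,
    duration: float,
    duration_range: tuple[float, float] = (10.0, 30.0),
    min_gap: float = 30.0,
    seed: int = 0,
    mode: str = "poisson",
    severity_range: tuple[float, float] = (0.3, 1.0),
    lag_range: tuple[float, float] = (10.0, 20.0),
    baseline_spo2: float = 97.0,
) -> list[ApneaEvent]:
    """Draw a non-overlapping apnea event schedule at a target AHI.

    ``mode="fixed"`` places exactly ``round(ahi * duration / 3600)`` events
    (deterministic count, for tests); ``mode="poisson"`` draws the count from
    the Poisson law with that mean, which is how independently occurring
    events arrive in time.

    Raises
    ------
    SchedulingError
        If the drawn events plus minimum gaps cannot fit into the record.
    """
    if ahi < 0:
        raise ValueError(f"ahi must be >= 0, got {ahi}")
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(seed)
    mean_count = ahi * duration / 3600.0
    if mode == "fixed":
        n = int(round(mean_count))
    elif mode == "poisson":
        n = int(rng.poisson(mean_count))
    else:
        raise ValueError(f"unknown scheduling mode {mode!r}")
    if n == 0:
        return []

    durs = rng.uniform(*duration_range, size=n)
    total = durs.sum() + (n - 1) * min_gap
    if total > duration:
        raise SchedulingError(
            f"{n} events of total length {total:.0f} s (incl. gaps) do not fit in {duration:.0f} s"
        )
    # distribute the slack over the n+1 inter-event intervals
    slack = duration - total
    cuts = np.sort(rng.uniform(0.0, slack, size=n))
    onsets = cuts + np.concatenate(([0.0], np.cumsum(durs[:-1] + min_gap)))

    sev = rng.uniform(*severity_range, size=n)
    lag = rng.uniform(*lag_range, size=n)
    events = [
        ApneaEvent(
            onset=float(onsets[i]),
            duration=float(durs[i]),
            severity=float(sev[i]),
            desat_lag=float(lag[i]),
            nadir_spo2=float(_nadir_for(sev[i], baseline_spo2)),
        )
        for i in range(n)
    ]
    return validate_events(events, duration=duration, min_gap=0.0, duration_range=duration_range)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

def _beat_schedule(
    profile: SubjectProfile, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Beat onset times covering [0, duration] (last beat ends past the end)."""
    base = 60.0 / profile.hr_bpm
    n_max = int(math.ceil(duration / 0.33)) + 8  # ibi is clipped at 0.33 s
    eps = rng.standard_normal(n_max)
    phi_lf = rng.uniform(0, 2 * np.pi)
    starts = [0.0]
    t = 0.0
    i = 0
    while t <= duration and i < n_max:
        mod = (
            0.5 * np.sin(2 * np.pi * t / profile.resp_period)
            + 0.3 * np.sin(2 * np.pi * 0.095 * t + phi_lf)
            + 0.6 * eps[i]
        )
        ibi = base * (1.0 + profile.hrv_scale * mod) if profile.hrv_scale > 0 else base
        ibi = min(max(ibi, 0.33), 2.0)
        t += ibi
        starts.append(t)
        i += 1
    return np.asarray(starts)


def _render_channel(
    morphology: BeatMorphology,
    starts: np.ndarray,
    duration: float,
    rate: float,
    amp_per_beat: np.ndarray,
    noise_std: float,
    resp_period: float,
    wander_amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 2)
    periods = np.diff(starts)
    phase = (t - starts[idx]) / periods[idx]
    y = amp_per_beat[idx] * beat_value(morphology, phase)
    if wander_amp > 0:
        y = y + wander_amp * np.sin(2 * np.pi * t / resp_period)
    if noise_std > 0:
        y = y + noise_std * rng.standard_normal(n)
    return y


def simulate_subject(
    profile: SubjectProfile,
    duration: float,
    events: Sequence[ApneaEvent] = (),
    seed: int = 0,
    rates: Optional[dict[str, float]] = None,
    record_id: str = "sim",
) -> WaveformRecord:
    """Simulate one subject's recording; events (if any) are injected afterwards.

    Both pulse channels share one cardiac clock, so their beat-interval series
    agree by construction — the property the wrist nanogenerator was validated
    on against PPG. Reproducible: identical (profile, events, seed) give
    bit-identical output.
    """
    base_period = 60.0 / profile.hr_bpm
    if duration < base_period:
        raise ValueError(f"duration {duration} s is shorter than one beat ({base_period:.2f} s)")
    rates = dict(DEFAULT_RATES if rates is None else rates)

    ss = np.random.SeedSequence(seed)
    rng_beats, rng_ppw, rng_ppg, rng_spo2, rng_amp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    starts = _beat_schedule(profile, duration, rng_beats)
    n_beats = len(starts) - 1
    # respiratory amplitude modulation + small per-beat jitter, shared clock
    amp = 1.0 + profile.resp_amp_mod * np.sin(2 * np.pi * starts[:-1] / profile.resp_period)
    if profile.resp_amp_mod > 0:
        amp = amp * (1.0 + 0.02 * rng_amp.standard_normal(n_beats))
    amp = np.concatenate([amp, amp[-1:]])  # guard value for the trailing beat

    channels: dict[str, np.ndarray] = {}
    channels[PPW] = _render_channel(
        profile.morphologies[PPW], starts, duration, rates[PPW], amp,
        profile.ppw_noise, profile.resp_period, 0.03, rng_ppw,
    )
    channels[PPG] = _render_channel(
        profile.morphologies[PPG], starts, duration, rates[PPG], amp,
        profile.ppg_noise, profile.resp_period, 0.03, rng_ppg,
    )

    n_spo2 = int(round(duration * rates[SPO2]))
    if profile.spo2_noise > 0:
        # slow wander: smoothed white noise, bounded so variation stays < 2 %
        raw = rng_spo2.standard_normal(n_spo2 + 40)
        kernel = np.exp(-0.5 * (np.arange(-15, 16) / 5.0) ** 2)
        kernel /= kernel.sum()
        slow = np.convolve(raw, kernel, mode="same")[20 : 20 + n_spo2]
        slow = slow / max(np.std(slow), 1e-12) * profile.spo2_noise
        slow = np.clip(slow, -0.8, 0.8)
    else:
        slow = np.zeros(n_spo2)
    channels[SPO2] = np.clip(profile.spo2_baseline + slow, 50.0, 100.0)

    # systolic peak times (ground truth for peak-detector oracles)
    sys_center = {
        name: profile.morphologies[name].systolic.center for name in (PPW, PPG)
    }
    beat_peaks = starts[:-1] + np.diff(starts) * sys_center[PPG]

    record = WaveformRecord(
        channels=channels,
        rates=rates,
        duration=duration,
        events=[],
        seed=seed,
        profile=profile,
        beat_times=beat_peaks,
        record_id=record_id,
    )
    if events:
        record = apply_apnea_modulation(record, events)
    return record


# ---------------------------------------------------------------------------
# apnea modulation
# ---------------------------------------------------------------------------

#: amplitude gain floors at severity 1: PPW drops by > 50 %, PPG by 30-50 %
_PPW_DROP = 0.60
_PPG_DROP = 0.40
#: onset/offset ramp of the amplitude suppression (s)
_RAMP = 3.0
#: compensatory overshoot magnitude at severity 1 (fraction above baseline)
_OVERSHOOT = 0.10
#: post-event amplitude recovery window (s)
_AMP_RECOVERY = 15.0
#: time from decline start to the desaturation nadir and back (s)
_DESAT_FALL_MIN = 4.0
_DESAT_RECOVERY = 20.0


def _amplitude_gain(t: np.ndarray, ev: ApneaEvent, drop: float) -> np.ndarray:
    """Multiplicative gain profile of one event; exactly 1 outside its window."""
    g = np.ones_like(t)
    gmin = 1.0 - drop * ev.severity
    t0, t1 = ev.onset, ev.end
    ramp = min(_RAMP, ev.duration / 2)
    # cosine ramp down, hold at gmin
    m = (t >= t0) & (t < t0 + ramp)
    u = (t[m] - t0) / ramp
    g[m] = 1.0 + (gmin - 1.0) * 0.5 * (1 - np.cos(np.pi * u))
    m = (t >= t0 + ramp) & (t < t1)
    g[m] = gmin
    # recovery with a bounded compensatory overshoot, returning exactly to 1
    ov = _OVERSHOOT * ev.severity
    rec = _AMP_RECOVERY
    m = (t >= t1) & (t < t1 + rec)
    u = (t[m] - t1) / rec
    # rises from gmin through 1 + ov and decays back to 1 at u = 1
    g[m] = 1.0 + (gmin - 1.0) * (1 - u) ** 2 + ov * np.sin(np.pi * u) * (1 - u)
    return g


def _desat_depth(t: np.ndarray, ev: ApneaEvent, baseline: float) -> np.ndarray:
    """Desaturation depth (%) to subtract; exactly 0 outside [t0, t_end]."""
    depth = max(0.0, baseline - ev.nadir_spo2)
    d = np.zeros_like(t)
    if depth == 0:
        return d
    t0 = ev.onset + ev.desat_lag
    t_nadir = max(ev.end + 5.0, t0 + _DESAT_FALL_MIN)
    t_end = t_nadir + _DESAT_RECOVERY
    m = (t >= t0) & (t < t_nadir)  # linear monotone decline
    d[m] = depth * (t[m] - t0) / (t_nadir - t0)
    m = (t >= t_nadir) & (t < t_end)  # linear re-saturation
    d[m] = depth * (1.0 - (t[m] - t_nadir) / _DESAT_RECOVERY)
    return d


def modulation_windows(ev: ApneaEvent) -> tuple[float, float]:
    """[start, stop] of the span an event may alter (event + recovery tails)."""
    t0 = ev.onset
    amp_end = ev.end + _AMP_RECOVERY
    desat_end = max(ev.end + 5.0, ev.onset + ev.desat_lag + _DESAT_FALL_MIN) + _DESAT_RECOVERY
    return t0, max(amp_end, desat_end)


def apply_apnea_modulation(
    record: WaveformRecord, events: Sequence[ApneaEvent]
) -> WaveformRecord:
    """Inject apnea signatures into a clean record.

    Within each event the PPW envelope falls to at most half its local
    baseline and the PPG envelope to 50-70 % of it; SpO2 declines
    monotonically from ``onset + desat_lag`` to the event's nadir and then
    recovers linearly. A bounded compensatory overshoot follows each event.
    Samples outside event + recovery windows are returned bit-identical.
    """
    if not events:
        return record
    events = validate_events(events, duration=record.duration, min_gap=0.0)
    out = record.copy()

    for name, drop in ((PPW, _PPW_DROP), (PPG, _PPG_DROP)):
        t = out.times(name)
        gain = np.ones_like(t)
        for ev in events:
            gain *= _amplitude_gain(t, ev, drop)
        out.channels[name] = out.channels[name] * gain

    t = out.times(SPO2)
    spo2 = out.channels[SPO2]
    total_depth = np.zeros_like(t)
    spo2_rate = out.rates[SPO2]
    for ev in events:
        i1 = int(ev.onset * spo2_rate)
        i0 = max(0, i1 - int(60 * spo2_rate))
        local_base = float(np.mean(spo2[i0 : max(i0 + 1, i1)]))
        total_depth += _desat_depth(t, ev, local_base)
    out.channels[SPO2] = np.clip(spo2 - total_depth, 50.0, 100.0)

    out.events = list(events)
    return out
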