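"""Benchmark dataset builders on top of the simulator.

The standard benchmark mirrors the balanced clinical design at synthetic
scale: equal numbers of apnea-containing and normal 2-min segments, each
simulated for a fresh subject profile drawn from normal sleep physiology
(60-100 bpm, SpO2 baseline 95-99 %, 3-5 s breathing cycle), with one
apnea event of configurable severity injected into every positive segment.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .preprocess import Segment, segment_record
from .record import ApneaEvent
from .synth import SubjectProfile, _nadir_for, simulate_subject

__all__ = ["make_benchmark", "make_night_record"]


def _draw_profile(rng: np.random.Generator, noise_scale: float = 1.0) -> SubjectProfile:
    return SubjectProfile(
        hr_bpm=float(rng.uniform(62.0, 98.0)),
        hrv_scale=float(rng.uniform(0.02, 0.05)),
        spo2_baseline=float(rng.uniform(95.5, 98.5)),
        spo2_noise=0.15 * noise_scale,
        resp_period=float(rng.uniform(3.2, 4.8)),
        ppw_noise=0.02 * noise_scale,
        ppg_noise=0.02 * noise_scale,
    )


def make_benchmark(
    n_per_class: int = 500,
    severity: float = 1.0,
    seed: int = 7,
    window: float = 120.0,
    noise_scale: float = 1.0,
    min_event_duration: float = 10.0,
    max_event_duration: float = 30.0,
) -> tuple[list[Segment], np.ndarray]:
    """Balanced labeled 2-min segments for classifier training/evaluation.

    Each segment is an independent 120 s simulation; positives carry one
    event of the requested severity placed so that it overlaps the window by
    well over the 5 s labeling minimum. Fully deterministic in ``seed``.

    Returns
    -------
    (segments, labels) with labels[i] = 1 for apnea-containing.
    """
    root = np.random.SeedSequence(seed)
    seg_seeds = root.spawn(2 * n_per_class)
    rng = np.random.default_rng(root.spawn(1)[0])
    segments: list[Segment] = []
    labels = np.zeros(2 * n_per_class, dtype=int)

    for i in range(2 * n_per_class):
        positive = i < n_per_class
        profile = _draw_profile(rng, noise_scale)
        events = []
        if positive:
            dur = float(rng.uniform(min_event_duration, max_event_duration))
            onset = float(rng.uniform(5.0, window - dur - 5.0))
            events = [
                ApneaEvent(
                    onset=onset,
                    duration=dur,
                    severity=severity,
                    desat_lag=float(rng.uniform(10.0, 20.0)),
                    nadir_spo2=_nadir_for(severity, profile.spo2_baseline),
                )
            ]
        child_seed = int(seg_seeds[i].generate_state(1)[0] % (2**31))
        rec = simulate_subject(
            profile, window, events=events, seed=child_seed, record_id=f"bench-{i}"
        )
        seg = segment_record(rec, window=window)[0]
        segments.append(seg)
        labels[i] = int(seg.label)
    return segments, labels


def make_night_record(
    duration_h: float = 2.0,
    ahi: float = 10.0,
    severity_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    profile: Optional[SubjectProfile] = None,
):
    """One continuous multi-hour recording with a Poisson event schedule —
    the input for streaming-cascade experiments."""
    from .synth import schedule_events

    ss = np.random.SeedSequence(seed)
    s_prof, s_events, s_sim = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    if profile is None:
        profile = _draw_profile(np.random.default_rng(s_prof))
    duration = duration_h * 3600.0
    events = schedule_events(
        ahi=ahi,
        duration=duration,
        min_gap=60.0,
        seed=s_events,
        severity_range=severity_range,
        baseline_spo2=profile.spo2_baseline,
    )
    return simulate_subject(profile, duration, events=events, seed=s_sim, record_id="night")
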