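"""Core data containers: multi-rate physiological recordings and apnea event annotations.

A :class:`WaveformRecord` holds three channels sampled at different rates —
the piezoelectric pulse pressure wave (PPW, wrist nanogenerator), the optical
photoplethysmogram (PPG) and the oxygen-saturation trace (SpO2) — together
with ground-truth apnea event annotations when the record is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: canonical channel names used throughout the package
PPW = "PPW"
PPG = "PPG"
SPO2 = "SpO2"

#: default sampling rates in Hz
DEFAULT_RATES = {PPW: 50.0, PPG: 256.0, SPO2: 1.0}


@dataclass(frozen=True)
class ApneaEvent:
    """One respiratory event: an apnea (or hypopnea) episode.

    Parameters
    ----------
    onset : float
        Event start, seconds from the beginning of the record.
    duration : float
        Event length in seconds; physiological events last roughly 10-30 s.
    severity : float
        Dimensionless severity in [0, 1] scaling the pulse-amplitude
        suppression and the oxygen desaturation depth.
    desat_lag : float
        Delay, in seconds, between event onset and the start of the SpO2
        decline (circulatory transport delay, typically 10-20 s).
    nadir_spo2 : float
        Lowest SpO2 (%) the desaturation reaches.
    subtype : str
        Informational tag ("obstructive", "central", ...). Not used by any
        computation.
    """

    onset: float
    duration: float
    severity: float
    desat_lag: float
    nadir_spo2: float
    subtype: str = "obstructive"

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")
        if self.desat_lag < 0:
            raise ValueError(f"desat_lag must be >= 0, got {self.desat_lag}")
        if not 0.0 < self.nadir_spo2 < 100.0:
            raise ValueError(f"nadir_spo2 must lie in (0, 100), got {self.nadir_spo2}")

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def overlap(self, start: float, stop: float) -> float:
        """Length (s) of the intersection of this event with [start, stop]."""
        return max(0.0, min(self.end, stop) - max(self.onset, start))


def validate_events(
    events: list[ApneaEvent] | tuple[ApneaEvent, ...],
    duration: Optional[float] = None,
    min_gap: float = 0.0,
    duration_range: Optional[tuple[float, float]] = None,
    severe_cutoff: float = 0.7,
) -> list[ApneaEvent]:
    """Check a list of events for mutual consistency and return it sorted.

    Events must be pairwise non-overlapping with at least ``min_gap`` seconds
    between them; an event with severity above ``severe_cutoff`` must
    desaturate below 90 %.

    Raises
    ------
    ValueError
        On overlap, out-of-range duration, or a severe event whose nadir does
        not drop below 90 %.
    """
    evs = sorted(events, key=lambda e: e.onset)
    for i, ev in enumerate(evs):
        if duration is not None and ev.end > duration:
            raise ValueError(f"event {i} ends at {ev.end:.1f} s, past record end {duration:.1f} s")
        if duration_range is not None and not (duration_range[0] <= ev.duration <= duration_range[1]):
            raise ValueError(
                f"event {i} duration {ev.duration:.1f} s outside configured range {duration_range}"
            )
        if ev.severity >= severe_cutoff and ev.nadir_spo2 >= 90.0:
            raise ValueError(
                f"event {i} has severity {ev.severity:.2f} >= {severe_cutoff} but "
                f"nadir {ev.nadir_spo2:.1f} % >= 90 %"
            )
        if i > 0 and ev.onset < evs[i - 1].end + min_gap:
            raise ValueError(
                f"events {i - 1} and {i} overlap or are closer than min_gap={min_gap} s"
            )
    return evs


@dataclass
class WaveformRecord:
    """A multi-channel, multi-rate recording with event annotations.

    ``channels`` maps channel name -> 1-D float array; ``rates`` maps the same
    names -> sampling rate (Hz). ``beat_times`` carries the simulator's
    ground-truth cardiac clock (systolic peak times, s) when available.
    """

    channels: dict[str, np.ndarray]
    rates: dict[str, float]
    duration: float
    events: list[ApneaEvent] = field(default_factory=list)
    seed: Optional[int] = None
    profile: Optional[object] = None  # SubjectProfile snapshot (kept opaque here)
    beat_times: Optional[np.ndarray] = None
    validity: Optional[dict[str, np.ndarray]] = None  # True = valid sample
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.channels) != set(self.rates):
            raise ValueError("channels and rates must list the same channel names")
        for name, x in self.channels.items():
            n_expected = self.rates[name] * self.duration
            if abs(len(x) - n_expected) > 1:
                raise ValueError(
                    f"channel {name}: {len(x)} samples, expected "
                    f"{n_expected:.0f} (= {self.rates[name]} Hz x {self.duration} s)"
                )
            if not np.all(np.isfinite(x)):
                raise ValueError(f"channel {name} contains non-finite samples")
        if SPO2 in self.channels:
            s = self.channels[SPO2]
            if s.size and (s.min() < 50.0 or s.max() > 100.0):
                raise ValueError("SpO2 samples must lie in [50, 100] %")

    def times(self, channel: str) -> np.ndarray:
        """Sample times (s) for one channel."""
        return np.arange(len(self.channels[channel])) / self.rates[channel]

    def copy(self) -> "WaveformRecord":
        return replace(
            self,
            channels={k: v.copy() for k, v in self.channels.items()},
            rates=dict(self.rates),
            events=list(self.events),
            beat_times=None if self.beat_times is None else self.beat_times.copy(),
            validity=None
            if self.validity is None
            else {k: v.copy() for k, v in self.validity.items()},
        )

    def crop(self, start: float, stop: float) -> dict[str, np.ndarray]:
        """Per-channel sample slices covering [start, stop)."""
        out = {}
        for name, x in self.channels.items():
            r = self.rates[name]
            out[name] = x[int(round(start * r)) : int(round(stop * r))]
        return out
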