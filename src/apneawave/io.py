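"""File I/O: EDF+ recordings, JSON events/reports, CSV features, YAML profiles.

EDF (European Data Format) is the interchange standard of the PSG world and
handles the package's multi-rate channel layout natively: each 1 s data
record carries 50 PPW, 256 PPG and 1 SpO2 sample. Events ride in an EDF+
annotation channel as standard onset/duration/label triplets (label
``apnea``, with the simulator's severity/lag/nadir parameters appended as
``key=value`` tokens so synthetic ground truth survives a round trip).

The codec implements the published 16-bit EDF layout directly: samples are
quantized to the per-channel physical range, so write-then-read reproduces
every sample within one quantization step and annotations exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .record import PPG, PPW, SPO2, ApneaEvent, WaveformRecord
from .synth import BeatComponent, BeatMorphology, SubjectProfile

__all__ = [
    "ParseError",
    "write_edf",
    "read_edf",
    "events_to_json",
    "events_from_json",
    "write_features_csv",
    "read_features_csv",
    "profile_to_yaml",
    "profile_from_yaml",
    "provenance",
]


class ParseError(ValueError):
    """Malformed file; message names the offending byte offset / field."""


# ---------------------------------------------------------------------------
# EDF+
# ---------------------------------------------------------------------------

_ANNOT_SAMPLES = 120  # 2-byte units per record reserved for annotations


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_num(x: float, width: int = 8) -> bytes:
    for fmt in (f"{x:.8g}", f"{x:.6g}", f"{x:.4g}", f"{x:.2f}", f"{x:.0f}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {x} in {width} ascii chars")


def _event_label(ev: ApneaEvent) -> str:
    return (
        f"apnea sev={ev.severity!r} lag={ev.desat_lag!r} "
        f"nadir={ev.nadir_spo2!r} sub={ev.subtype}"
    )


def _event_from_label(label: str, onset: float, duration: float) -> Optional[ApneaEvent]:
    parts = label.split()
    if not parts or parts[0] != "apnea":
        return None
    kv = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
    return ApneaEvent(
        onset=onset,
        duration=duration,
        severity=float(kv.get("sev", 1.0)),
        desat_lag=float(kv.get("lag", 15.0)),
        nadir_spo2=float(kv.get("nadir", 89.0)),
        subtype=kv.get("sub", "obstructive"),
    )


def write_edf(record: WaveformRecord, path) -> None:
    """Write a record as EDF+C with one signal per channel plus annotations.

    The record duration is padded up to whole seconds (EDF data records are
    1 s here); each channel's physical range is taken from its data, giving
    16-bit quantization over the actual signal span.
    """
    path = Path(path)
    names = list(record.channels)
    n_records = int(np.ceil(record.duration))
    rates = {n: record.rates[n] for n in names}
    for n, r in rates.items():
        if abs(r - round(r)) > 1e-9:
            raise ValueError(f"EDF writer needs integer Hz rates; channel {n} has {r}")

    phys: dict[str, tuple[float, float]] = {}
    digital: dict[str, np.ndarray] = {}
    for n in names:
        x = np.asarray(record.channels[n], dtype=float)
        want = int(round(rates[n])) * n_records
        if len(x) < want:  # pad the trailing partial second
            x = np.concatenate([x, np.full(want - len(x), x[-1] if len(x) else 0.0)])
        if n == SPO2:
            lo, hi = 0.0, 100.0
        else:
            lo, hi = float(x.min()), float(x.max())
            if hi - lo < 1e-9:
                lo, hi = lo - 1.0, hi + 1.0
            # pad so the ASCII-rounded header range still encloses the data,
            # then quantize against the range actually written: write-then-
            # read stays within one quantization step, with no clipping
            pad = 0.005 * (hi - lo)
            lo, hi = lo - pad, hi + pad
        lo, hi = (float(_fmt_num(v).decode().strip()) for v in (lo, hi))
        phys[n] = (lo, hi)
        scale = (hi - lo) / 65535.0
        digital[n] = np.clip(np.round((x - lo) / scale) - 32768, -32768, 32767).astype("<i2")

    ns = len(names) + 1  # + annotation signal
    header_bytes = 256 * (1 + ns)
    head = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii(f"Startdate X X X X {record.record_id}"[:80], 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(header_bytes, 8),
            _ascii("EDF+C", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )

    labels = names + ["EDF Annotations"]
    spr = [int(round(rates[n])) for n in names] + [_ANNOT_SAMPLES]
    dims = {PPW: "mV", PPG: "au", SPO2: "%"}
    sig_head = b"".join(
        [
            b"".join(_ascii(lb, 16) for lb in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii(dims.get(n, "au"), 8) for n in names) + _ascii("", 8),
            b"".join(_fmt_num(phys[n][0]) for n in names) + _fmt_num(-1),
            b"".join(_fmt_num(phys[n][1]) for n in names) + _fmt_num(1),
            b"".join(_ascii(-32768, 8) for _ in labels),
            b"".join(_ascii(32767, 8) for _ in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii(s, 8) for s in spr),
            b"".join(_ascii("", 32) for _ in labels),
        ]
    )

    # assign each event TAL to the data record containing its onset
    tals: dict[int, list[bytes]] = {}
    for ev in sorted(record.events, key=lambda e: e.onset):
        rec_idx = min(n_records - 1, int(ev.onset))
        tal = f"+{ev.onset:.4g}\x15{ev.duration:.4g}\x14{_event_label(ev)}\x14\x00"
        tals.setdefault(rec_idx, []).append(tal.encode("utf-8"))

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        for rec in range(n_records):
            for n in names:
                r = int(round(rates[n]))
                fh.write(digital[n][rec * r : (rec + 1) * r].tobytes())
            block = f"+{rec}\x14\x14\x00".encode("ascii") + b"".join(tals.get(rec, []))
            if len(block) > 2 * _ANNOT_SAMPLES:
                raise ValueError(
                    f"annotations for record {rec} exceed the reserved "
                    f"{2 * _ANNOT_SAMPLES} bytes"
                )
            fh.write(block.ljust(2 * _ANNOT_SAMPLES, b"\x00"))


def _parse_tals(raw: bytes) -> list[tuple[float, float, str]]:
    out = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        fields = tal.split(b"\x14")
        if len(fields) < 2:
            continue
        time_part = fields[0]
        if b"\x15" in time_part:
            onset_b, dur_b = time_part.split(b"\x15", 1)
            duration = float(dur_b)
        else:
            onset_b, duration = time_part, 0.0
        onset = float(onset_b)
        for label in fields[1:]:
            if label:
                out.append((onset, duration, label.decode("utf-8")))
    return out


def read_edf(path) -> WaveformRecord:
    """Read an EDF/EDF+ file with the package's channel layout back into a
    :class:`WaveformRecord`. Annotated apnea events are reconstructed,
    including simulator parameters when present in the label."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 256:
        raise ParseError(f"{path}: truncated header ({len(data)} bytes < 256)")

    def field(off: int, width: int, name: str) -> str:
        return data[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(field(236, 8, "n_records"))
        rec_dur = float(field(244, 8, "record_duration"))
        ns = int(field(252, 4, "ns"))
    except ValueError as exc:
        raise ParseError(f"{path}: bad numeric header field near byte 236: {exc}") from exc
    header_bytes = int(field(184, 8, "header_bytes"))
    if header_bytes != 256 * (1 + ns):
        raise ParseError(
            f"{path}: header-bytes field at offset 184 says {header_bytes}, "
            f"expected {256 * (1 + ns)} for {ns} signals"
        )

    off = 256
    labels = [field(off + 16 * i, 16, "label") for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns  # skip transducer, phys dim
    pmin = [float(field(off + 8 * i, 8, "phys_min")) for i in range(ns)]
    off += 8 * ns
    pmax = [float(field(off + 8 * i, 8, "phys_max")) for i in range(ns)]
    off += 8 * ns
    dmin = [int(field(off + 8 * i, 8, "dig_min")) for i in range(ns)]
    off += 8 * ns
    dmax = [int(field(off + 8 * i, 8, "dig_max")) for i in range(ns)]
    off += 8 * ns + 80 * ns
    spr = [int(field(off + 8 * i, 8, "samples_per_record")) for i in range(ns)]

    rec_len = 2 * sum(spr)
    body = data[header_bytes:]
    if len(body) < rec_len * n_records:
        raise ParseError(
            f"{path}: body holds {len(body)} bytes, need {rec_len * n_records} "
            f"for {n_records} records of {rec_len} bytes"
        )

    chans: dict[str, list[np.ndarray]] = {lb: [] for lb in labels}
    annot_raw = b""
    for rec in range(n_records):
        base = rec * rec_len
        pos = 0
        for i, lb in enumerate(labels):
            chunk = body[base + pos : base + pos + 2 * spr[i]]
            if lb == "EDF Annotations":
                annot_raw += chunk
            else:
                chans[lb].append(np.frombuffer(chunk, dtype="<i2"))
            pos += 2 * spr[i]

    channels: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    for i, lb in enumerate(labels):
        if lb == "EDF Annotations":
            continue
        dig = np.concatenate(chans[lb]).astype(float)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        channels[lb] = pmin[i] + (dig - dmin[i]) * scale
        rates[lb] = spr[i] / rec_dur

    events = []
    for onset, duration, label in _parse_tals(annot_raw):
        ev = _event_from_label(label, onset, duration)
        if ev is not None:
            events.append(ev)

    duration = n_records * rec_dur
    if SPO2 in channels:
        channels[SPO2] = np.clip(channels[SPO2], 50.0, 100.0)
    return WaveformRecord(
        channels=channels,
        rates=rates,
        duration=duration,
        events=sorted(events, key=lambda e: e.onset),
        record_id=path.stem,
    )


# ---------------------------------------------------------------------------
# JSON / CSV / YAML
# ---------------------------------------------------------------------------

def events_to_json(events: Sequence[ApneaEvent], path, seed: Optional[int] = None) -> None:
    payload = {
        "provenance": provenance(seed=seed),
        "events": [dataclasses.asdict(ev) for ev in events],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def events_from_json(path) -> list[ApneaEvent]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at char {exc.pos}: {exc.msg}") from exc
    items = payload["events"] if isinstance(payload, dict) else payload
    return [ApneaEvent(**item) for item in items]


def write_features_csv(table, path) -> None:
    table.to_csv(path, index=False)


def read_features_csv(path):
    import pandas as pd

    return pd.read_csv(path)


def profile_to_yaml(profile: SubjectProfile, path) -> None:
    d = dataclasses.asdict(profile)
    d["morphologies"] = {
        kind: {
            "kind": m.kind,
            "components": [dataclasses.asdict(c) for c in m.components],
            "decay_amp": m.decay_amp,
            "decay_tau": m.decay_tau,
        }
        for kind, m in profile.morphologies.items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def profile_from_yaml(path) -> SubjectProfile:
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    morphs = {}
    for kind, m in d.pop("morphologies", {}).items():
        morphs[kind] = BeatMorphology(
            kind=m["kind"],
            components=tuple(BeatComponent(**c) for c in m["components"]),
            decay_amp=m.get("decay_amp", 0.0),
            decay_tau=m.get("decay_tau", 0.12),
        )
    if morphs:
        d["morphologies"] = morphs
    return SubjectProfile(**d)


def provenance(seed: Optional[int] = None, config: Optional[dict] = None) -> dict:
    """Machine-readable provenance block embedded in every structured output."""
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "package": "apneawave",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:12] if blob else None,
    }
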