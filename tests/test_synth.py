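"""Simulator tests: beat rendering, event scheduling, apnea modulation."""

import numpy as np
import pytest
import scipy.signal

import apneawave as aw
from apneawave.record import PPG, PPW, SPO2
from apneawave.synth import _nadir_for, modulation_windows


# ---------------------------------------------------------------------------
# render_beat
# ---------------------------------------------------------------------------

def test_render_beat_length_and_global_max():
    m = aw.default_morphology(PPG)
    beat = aw.render_beat(m, period=1.0, rate=50.0)
    assert len(beat) == 50
    # global maximum sits at the systolic component center
    assert abs(np.argmax(beat) / 50.0 - m.systolic.center) < 0.05
    assert np.all(np.isfinite(beat))
    # returns close to baseline (0) at beat end
    assert beat[-1] <= 0.05 * beat.max()


def test_render_beat_single_component_unimodal():
    m = aw.BeatMorphology(kind=PPG, components=(aw.BeatComponent(1.0, 0.2, 0.05),))
    beat = aw.render_beat(m, 1.0, 100.0)
    peaks, _ = scipy.signal.find_peaks(beat)
    assert len(peaks) == 1


def test_render_beat_dicrotic_ratio_dense_grid_oracle():
    """Post-notch local max / global max = dicrotic amplitude, checked on a
    10x oversampled analytic grid."""
    m = aw.BeatMorphology(
        kind=PPG,
        components=(aw.BeatComponent(1.0, 0.17, 0.05), aw.BeatComponent(0.3, 0.52, 0.05)),
    )
    rate = 100.0
    beat = aw.render_beat(m, 1.0, rate)
    dense = aw.beat_value(m, np.linspace(0, 1, int(10 * rate), endpoint=False))
    for y in (beat, dense):
        peaks, _ = scipy.signal.find_peaks(y)
        assert len(peaks) == 2
        ratio = y[peaks[1]] / y[peaks[0]]
        assert ratio == pytest.approx(0.3, rel=0.02)
    # implementation matches the dense-grid oracle at shared sample points
    assert np.allclose(beat, dense[::10], atol=1e-12)


@pytest.mark.parametrize("period,rate", [(0.0, 50.0), (-1.0, 50.0), (1.0, 0.0)])
def test_render_beat_rejects_nonpositive(period, rate):
    with pytest.raises(ValueError):
        aw.render_beat(aw.default_morphology(PPW), period, rate)


def test_morphology_invariants_enforced():
    with pytest.raises(ValueError):  # systolic not strictly greatest
        aw.BeatMorphology(kind=PPG, components=(
            aw.BeatComponent(0.5, 0.2, 0.05), aw.BeatComponent(0.5, 0.5, 0.05)))
    with pytest.raises(ValueError):  # centers not increasing
        aw.BeatMorphology(kind=PPG, components=(
            aw.BeatComponent(1.0, 0.5, 0.05), aw.BeatComponent(0.3, 0.2, 0.05)))


# ---------------------------------------------------------------------------
# schedule_events
# ---------------------------------------------------------------------------

def test_schedule_zero_rate_empty():
    assert aw.schedule_events(ahi=0.0, duration=3600.0) == []


def test_schedule_fixed_count():
    events = aw.schedule_events(ahi=15.0, duration=3600.0, mode="fixed", seed=1)
    assert len(events) == 15
    onsets = [ev.onset for ev in events]
    assert onsets == sorted(onsets)
    for a, b in zip(events, events[1:]):
        assert b.onset >= a.end  # non-overlapping
    assert all(0 <= ev.onset and ev.end <= 3600.0 for ev in events)
    assert all(10.0 <= ev.duration <= 30.0 for ev in events)


def test_schedule_poisson_count_monte_carlo_oracle():
    """Mean event count over many seeds matches the Poisson mean the schedule
    is drawn from (independent Monte-Carlo of the same law)."""
    counts = [len(aw.schedule_events(30.0, 3600.0, mode="poisson", seed=s, min_gap=10.0))
              for s in range(1000)]
    oracle = [int(np.random.default_rng(s).poisson(30.0)) for s in range(1000)]
    assert np.mean(counts) == pytest.approx(30.0, abs=3.0)
    assert counts == oracle  # the schedule count IS the stated Poisson draw


def test_schedule_infeasible_raises():
    with pytest.raises(aw.SchedulingError):
        aw.schedule_events(ahi=60.0, duration=600.0, mode="fixed", min_gap=60.0, seed=0)


# ---------------------------------------------------------------------------
# simulate_subject
# ---------------------------------------------------------------------------

def test_simulated_beat_count_matches_heart_rate():
    prof = aw.SubjectProfile(hr_bpm=60.0, hrv_scale=0.0, ppw_noise=0.0, ppg_noise=0.0)
    rec = aw.simulate_subject(prof, 120.0, seed=0)
    for name in (PPW, PPG):
        peaks = aw.detect_peaks(rec.channels[name], rec.rates[name])
        assert len(peaks) == pytest.approx(120, abs=2)


def test_simulation_deterministic(default_profile):
    a = aw.simulate_subject(default_profile, 60.0, seed=5)
    b = aw.simulate_subject(default_profile, 60.0, seed=5)
    for name in a.channels:
        assert np.array_equal(a.channels[name], b.channels[name])
    c = aw.simulate_subject(default_profile, 60.0, seed=6)
    assert not np.array_equal(a.channels[PPG], c.channels[PPG])


def test_zero_hrv_gives_metronomic_intervals():
    prof = aw.SubjectProfile(hr_bpm=75.0, hrv_scale=0.0)
    rec = aw.simulate_subject(prof, 60.0, seed=0)
    ibis = np.diff(rec.beat_times)
    assert np.allclose(ibis, 60.0 / 75.0, atol=1e-9)


def test_record_invariants(clean_record):
    rec = clean_record
    for name, x in rec.channels.items():
        assert abs(len(x) - rec.rates[name] * rec.duration) <= 1
        assert np.all(np.isfinite(x))
    spo2 = rec.channels[SPO2]
    assert 95.0 <= spo2.min() and spo2.max() <= 99.0
    assert np.ptp(spo2) < 2.0  # < 2 percentage points with no events


def test_profile_range_violations_rejected():
    for kwargs in ({"hr_bpm": 110.0}, {"spo2_baseline": 90.0}, {"resp_period": 8.0}):
        with pytest.raises(ValueError):
            aw.SubjectProfile(**kwargs)


# ---------------------------------------------------------------------------
# apply_apnea_modulation
# ---------------------------------------------------------------------------

def test_modulation_empty_events_is_identity(clean_record):
    out = aw.apply_apnea_modulation(clean_record, [])
    for name in clean_record.channels:
        assert np.array_equal(out.channels[name], clean_record.channels[name])


def test_modulation_identity_outside_windows(default_profile):
    ev = aw.ApneaEvent(onset=60.0, duration=20.0, severity=1.0,
                       desat_lag=14.0, nadir_spo2=85.0)
    base = aw.simulate_subject(default_profile, 180.0, seed=42)
    mod = aw.apply_apnea_modulation(base, [ev])
    lo, hi = modulation_windows(ev)
    for name in (PPW, PPG, SPO2):
        r = base.rates[name]
        i0, i1 = int(np.floor(lo * r)), int(np.ceil(hi * r)) + 1
        before = np.abs(mod.channels[name][:i0] - base.channels[name][:i0])
        after = np.abs(mod.channels[name][i1:] - base.channels[name][i1:])
        assert before.max(initial=0.0) == 0.0
        assert after.max(initial=0.0) == 0.0


def _peak_envelope(x, rate):
    times = aw.detect_peaks(x, rate)
    idx = np.round(times * rate).astype(int)
    return times, x[idx]


def test_modulation_envelope_oracle(event_record):
    """Severity-1 event: PPW envelope drops to <= 0.5x its pre-event level,
    PPG to within [0.5, 0.7]x (peak-envelope oracle on the rendered arrays)."""
    ev = event_record.events[0]
    for name, lo_bound, hi_bound in ((PPW, 0.0, 0.5), (PPG, 0.5, 0.7)):
        times, heights = _peak_envelope(event_record.channels[name], event_record.rates[name])
        baseline = np.median(heights[(times > 5.0) & (times < ev.onset)])
        in_event = heights[(times >= ev.onset + 4.0) & (times <= ev.end)]
        ratio = in_event.min() / baseline
        assert lo_bound <= ratio <= hi_bound, f"{name} envelope ratio {ratio:.3f}"


def test_modulation_spo2_severe_nadir_below_90(event_record):
    assert event_record.channels[SPO2].min() < 90.0


def test_modulation_desat_timing(event_record):
    """SpO2 minimum occurs at/after onset + lag; decline is monotone down to
    the nadir."""
    ev = event_record.events[0]
    spo2 = event_record.channels[SPO2]
    rate = event_record.rates[SPO2]
    t = np.arange(len(spo2)) / rate
    nadir_t = t[np.argmin(spo2)]
    assert nadir_t >= ev.onset + ev.desat_lag
    dec = spo2[(t >= ev.onset + ev.desat_lag + 1) & (t <= nadir_t)]
    assert np.all(np.diff(dec) <= 1e-9)


def test_modulation_rejects_overlapping_events(clean_record):
    e1 = aw.ApneaEvent(onset=30.0, duration=20.0, severity=0.5, desat_lag=12.0, nadir_spo2=92.0)
    e2 = aw.ApneaEvent(onset=40.0, duration=20.0, severity=0.5, desat_lag=12.0, nadir_spo2=92.0)
    with pytest.raises(ValueError):
        aw.apply_apnea_modulation(clean_record, [e1, e2])


def test_severe_event_nadir_rule():
    with pytest.raises(ValueError):
        aw.validate_events([aw.ApneaEvent(onset=0.0, duration=15.0, severity=0.9,
                                          desat_lag=12.0, nadir_spo2=93.0)])
    # the scheduler's nadir assignment always satisfies the rule
    assert _nadir_for(0.7, 99.0) < 90.0


# ---------------------------------------------------------------------------
# cross-channel properties
# ---------------------------------------------------------------------------

def test_cross_modal_interval_agreement_noise_free():
    """PPW and PPG share the cardiac clock: their peak-interval series agree
    with R^2 >= 0.99 on noise-free records."""
    from scipy.stats import linregress

    prof = aw.SubjectProfile(ppw_noise=0.0, ppg_noise=0.0, hrv_scale=0.04)
    rec = aw.simulate_subject(prof, 120.0, seed=9)
    ibi = {}
    for name in (PPW, PPG):
        pk = aw.detect_peaks(rec.channels[name], rec.rates[name])
        pk = pk[(pk > 0.5) & (pk < rec.duration - 0.5)]
        ibi[name] = np.diff(pk)
    n = min(len(ibi[PPW]), len(ibi[PPG]))
    r = linregress(ibi[PPW][:n], ibi[PPG][:n])
    assert r.rvalue ** 2 >= 0.99


def test_peak_detector_recovers_ground_truth_beats():
    """Across seeded noise-free records, detected beat count matches the
    simulator's ground truth in >= 99 % of records (interior window)."""
    prof = aw.SubjectProfile(ppw_noise=0.0, ppg_noise=0.0)
    hits = 0
    n_rec = 60
    for seed in range(n_rec):
        rec = aw.simulate_subject(prof, 120.0, seed=seed)
        truth = rec.beat_times
        truth = truth[(truth > 0.5) & (truth < rec.duration - 0.5)]
        det = aw.detect_peaks(rec.channels[PPG], rec.rates[PPG])
        det = det[(det > 0.5) & (det < rec.duration - 0.5)]
        hits += int(len(det) == len(truth))
    assert hits / n_rec >= 0.99
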