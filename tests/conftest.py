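import numpy as np
import pytest

import apneawave as aw


@pytest.fixture(scope="session")
def default_profile() -> aw.SubjectProfile:
    return aw.SubjectProfile()


@pytest.fixture(scope="session")
def clean_record(default_profile) -> aw.WaveformRecord:
    """120 s event-free recording at default physiology."""
    return aw.simulate_subject(default_profile, 120.0, seed=42)


@pytest.fixture(scope="session")
def event_record(default_profile) -> aw.WaveformRecord:
    """180 s recording with one severe apnea event."""
    ev = aw.ApneaEvent(onset=60.0, duration=20.0, severity=1.0,
                       desat_lag=14.0, nadir_spo2=85.0)
    return aw.simulate_subject(default_profile, 180.0, events=[ev], seed=42)


@pytest.fixture(scope="session")
def small_benchmark():
    """Balanced 80+80 segment dataset shared by the classifier tests."""
    segments, labels = aw.make_benchmark(n_per_class=80, severity=1.0, seed=11)
    return segments, labels


@pytest.fixture(scope="session")
def small_features(small_benchmark):
    segments, labels = small_benchmark
    table = aw.features_table(segments, include_hb=True)
    return table, np.asarray(labels)
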