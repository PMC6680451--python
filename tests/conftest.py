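import numpy as np
import pytest

from phraseseg.events import PitchEvent, PitchStream


def make_stream(rows, *, stimulus_id="s1", version="natural", total_duration=None):
    """Build a stream from (onset, duration, pitch) rows."""
    events = tuple(PitchEvent(onset=o, duration=d, pitch=p) for o, d, p in rows)
    if total_duration is None:
        total_duration = events[-1].offset if events else 0.0
    return PitchStream(
        stimulus_id=stimulus_id,
        version=version,
        events=events,
        total_duration=total_duration,
    )


def random_stream(rng: np.random.Generator, n_events=30, *, version="natural"):
    """Random non-overlapping stream with varied gaps and pitches."""
    rows = []
    t = float(rng.integers(0, 200))
    for _ in range(n_events):
        dur = float(rng.integers(80, 400))  # integer ms: exact per-ms oracles
        pitch = float(rng.uniform(90, 300))
        rows.append((t, dur, pitch))
        t += dur + float(rng.integers(0, 500))
    return make_stream(rows, version=version, total_duration=t + 100)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_tone_stream():
    return make_stream([(0, 1000, 100.0), (1000, 1000, 200.0)], total_duration=2000)
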