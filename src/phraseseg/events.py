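"""Pitch-event streams, keypress logs, per-stimulus acoustic statistics, and file I/O.

Time is measured in milliseconds from stimulus start.  An event occupies the
half-open interval ``[onset, onset + duration)``; gaps between consecutive
events are silences.  Pitch is fundamental frequency in Hz.

Supported event-file formats
----------------------------
``csv``
    Header ``onset_ms,duration_ms,pitch_hz``, comma-separated, UTF-8.
``textgrid``
    Praat TextGrid (long text form).  The first interval tier is read; an
    interval whose text parses as a positive number is an event with that
    pitch in Hz, any other text (or empty) is silence.
``pitchtier``
    Praat PitchTier (long text form).  Points mark event onsets; each event
    extends to the next point (the last event receives the median duration).
    This is a lossy convention — PitchTier carries no silence information.
``midi``
    Standard MIDI file (type 0 or 1), monophonic.  Note numbers are
    converted to Hz via ``440 * 2**((n - 69) / 12)``; overlapping notes are
    rejected.  Velocities are ignored.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, MonophonicityError, ParseError

__all__ = [
    "PitchEvent",
    "PitchStream",
    "StimulusStats",
    "KeyPressLog",
    "hz_to_mel",
    "midi_note_to_hz",
    "stimulus_stats",
    "read_events",
    "read_keypress_csv",
    "write_keypress_csv",
    "write_results",
    "read_results",
    "write_events_csv",
]

#: Grace window (ms) after stimulus end within which keypresses are accepted.
DEFAULT_GRACE_MS = 1000.0


@dataclass(frozen=True)
class PitchEvent:
    """One stable-pitch, syllable-like unit."""

    onset: float
    duration: float
    pitch: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DomainError(f"event duration must be > 0, got {self.duration}")
        if self.pitch <= 0:
            raise DomainError(f"event pitch must be > 0 Hz, got {self.pitch}")
        if self.onset < 0:
            raise DomainError(f"event onset must be >= 0, got {self.onset}")

    @property
    def offset(self) -> float:
        """End of the event interval (exclusive)."""
        return self.onset + self.duration


@dataclass(frozen=True)
class PitchStream:
    """Time-ordered pitch events for one stimulus version."""

    stimulus_id: str
    version: Literal["natural", "delexicalized"]
    events: tuple[PitchEvent, ...]
    total_duration: float

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if self.version not in ("natural", "delexicalized"):
            raise DomainError(f"unknown version {self.version!r}")
        for prev, cur in zip(events, events[1:]):
            if cur.onset < prev.onset:
                raise DomainError("events must be sorted by onset")
            if cur.onset < prev.offset:
                raise MonophonicityError(
                    f"events overlap at {cur.onset} ms (previous ends {prev.offset} ms)"
                )
        if events and self.total_duration < events[-1].offset:
            raise DomainError(
                "total_duration must cover the last event "
                f"({self.total_duration} < {events[-1].offset})"
            )

    def __len__(self) -> int:
        return len(self.events)

    def gaps(self) -> list[tuple[float, float]]:
        """Silent spans between consecutive events as (start, end) pairs."""
        out = []
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.onset > prev.offset:
                out.append((prev.offset, cur.onset))
        return out

    def shifted(self, delta_ms: float) -> "PitchStream":
        """Uniformly translate all events (and total_duration) by ``delta_ms``."""
        return replace(
            self,
            events=tuple(replace(e, onset=e.onset + delta_ms) for e in self.events),
            total_duration=self.total_duration + delta_ms,
        )


@dataclass(frozen=True)
class StimulusStats:
    """Acoustic summary of one stream (the per-stimulus table metrics)."""

    mean_pitch_hz: float
    sd_pitch_hz: float
    mean_pitch_mel: float
    sd_pitch_mel: float
    pitch_range_hz: float
    pitch_change_rate: float
    silence_proportion: float
    duration_s: float


@dataclass(frozen=True)
class KeyPressLog:
    """Raw keypresses of one participant for one stimulus version."""

    participant_id: str
    instruction: Literal["speech", "music"]
    stimulus_id: str
    version: Literal["natural", "delexicalized"]
    press_times: tuple[float, ...]
    baseline_rt: float
    grace_ms: float = DEFAULT_GRACE_MS
    total_duration: float | None = None

    def __post_init__(self) -> None:
        presses = tuple(float(t) for t in self.press_times)
        object.__setattr__(self, "press_times", presses)
        if self.instruction not in ("speech", "music"):
            raise DomainError(f"unknown instruction {self.instruction!r}")
        if self.version not in ("natural", "delexicalized"):
            raise DomainError(f"unknown version {self.version!r}")
        if not self.baseline_rt > 0:
            raise DomainError(f"baseline_rt must be > 0, got {self.baseline_rt}")
        if any(b <= a for a, b in zip(presses, presses[1:])):
            raise DomainError("press_times must be strictly increasing")
        if presses and (presses[0] < 0):
            raise DomainError("press times must be >= 0")
        if self.total_duration is not None and presses:
            limit = self.total_duration + self.grace_ms
            if presses[-1] > limit:
                raise DomainError(
                    f"press at {presses[-1]} ms exceeds stimulus end + grace ({limit} ms)"
                )


# ---------------------------------------------------------------------------
# Scales and statistics
# ---------------------------------------------------------------------------

def hz_to_mel(f_hz):
    """Convert Hz to mel, ``m = 2595 * log10(1 + f/700)`` (O'Shaughnessy).

    Accepts scalars or arrays; raises :class:`DomainError` on negative input.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise DomainError("frequency must be >= 0 Hz")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if np.isscalar(f_hz) else out


def midi_note_to_hz(note: float) -> float:
    """Equal-tempered pitch of a MIDI note number (A4 = 69 = 440 Hz)."""
    return 440.0 * 2.0 ** ((note - 69) / 12.0)


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, math.sqrt(var)


def stimulus_stats(stream: PitchStream, *, weighted: bool = True) -> StimulusStats:
    """Acoustic summary statistics of a stream.

    Pitch mean/SD are duration-weighted over events by default (a long
    syllable counts more); pass ``weighted=False`` for the per-event
    (unweighted) convention.  Mel statistics are computed on mel-transformed
    event pitches, not by transforming the Hz statistics.
    """
    if len(stream) < 2:
        raise InsufficientDataError("need at least 2 events for stimulus statistics")
    pitches = np.array([e.pitch for e in stream.events])
    durations = np.array([e.duration for e in stream.events])
    weights = durations if weighted else np.ones_like(durations)
    mean_hz, sd_hz = _weighted_mean_sd(pitches, weights)
    mean_mel, sd_mel = _weighted_mean_sd(hz_to_mel(pitches), weights)
    duration_s = stream.total_duration / 1000.0
    return StimulusStats(
        mean_pitch_hz=mean_hz,
        sd_pitch_hz=sd_hz,
        mean_pitch_mel=mean_mel,
        sd_pitch_mel=sd_mel,
        pitch_range_hz=float(pitches.max() - pitches.min()),
        pitch_change_rate=len(stream) / duration_s,
        silence_proportion=1.0 - float(durations.sum()) / stream.total_duration,
        duration_s=duration_s,
    )


# ---------------------------------------------------------------------------
# Event-file readers
# ---------------------------------------------------------------------------

def read_events(
    path: str | Path,
    format: str | None = None,
    *,
    stimulus_id: str | None = None,
    version: str = "natural",
    total_duration: float | None = None,
) -> PitchStream:
    """Read a pitch-event file into a :class:`PitchStream`.

    ``format`` is one of ``csv``, ``textgrid``, ``pitchtier``, ``midi``;
    when omitted it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = {
            ".csv": "csv",
            ".textgrid": "textgrid",
            ".pitchtier": "pitchtier",
            ".mid": "midi",
            ".midi": "midi",
        }.get(path.suffix.lower())
        if format is None:
            raise ParseError(f"cannot infer format from extension of {path.name}")
    readers = {
        "csv": _read_events_csv,
        "textgrid": _read_events_textgrid,
        "pitchtier": _read_events_pitchtier,
        "midi": _read_events_midi,
    }
    if format not in readers:
        raise ParseError(f"unknown event-file format {format!r}")
    events, file_duration = readers[format](path)
    if not events:
        raise ParseError(f"{path.name}: no events found")
    if total_duration is None:
        total_duration = file_duration if file_duration is not None else events[-1].offset
    return PitchStream(
        stimulus_id=stimulus_id or path.stem,
        version=version,  # type: ignore[arg-type]
        events=tuple(events),
        total_duration=total_duration,
    )


def _read_events_csv(path: Path) -> tuple[list[PitchEvent], float | None]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: {exc}") from exc
    required = {"onset_ms", "duration_ms", "pitch_hz"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path.name}: missing columns {sorted(required - set(df.columns))}"
        )
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                PitchEvent(
                    onset=float(getattr(row, "onset_ms")),
                    duration=float(getattr(row, "duration_ms")),
                    pitch=float(getattr(row, "pitch_hz")),
                )
            )
        except (TypeError, ValueError, DomainError) as exc:
            raise ParseError(f"{path.name}: line {i + 2}: {exc}") from exc
    events.sort(key=lambda e: e.onset)
    return events, None


def write_events_csv(stream: PitchStream, path: str | Path) -> None:
    """Write a stream in the canonical event-CSV dialect."""
    df = pd.DataFrame(
        {
            "onset_ms": [e.onset for e in stream.events],
            "duration_ms": [e.duration for e in stream.events],
            "pitch_hz": [e.pitch for e in stream.events],
        }
    )
    df.to_csv(path, index=False)


def _read_events_textgrid(path: Path) -> tuple[list[PitchEvent], float | None]:
    from ._praat import read_textgrid_intervals

    intervals, xmax = read_textgrid_intervals(path)
    events = []
    for xmin_s, xmax_s, text in intervals:
        text = text.strip()
        if not text:
            continue
        try:
            pitch = float(text)
        except ValueError:
            continue  # labelled but non-numeric intervals are silences
        if pitch <= 0:
            continue
        events.append(
            PitchEvent(onset=xmin_s * 1000.0, duration=(xmax_s - xmin_s) * 1000.0, pitch=pitch)
        )
    return events, xmax * 1000.0 if xmax is not None else None


def _read_events_pitchtier(path: Path) -> tuple[list[PitchEvent], float | None]:
    from ._praat import read_pitchtier_points

    points, xmax = read_pitchtier_points(path)
    if not points:
        return [], None
    onsets = [t * 1000.0 for t, _ in points]
    durations = [b - a for a, b in zip(onsets, onsets[1:])]
    if durations:
        last = statistics.median(durations)
    else:
        last = 100.0
    durations.append(last)
    events = [
        PitchEvent(onset=o, duration=d, pitch=v)
        for (o, d, (_, v)) in zip(onsets, durations, points)
    ]
    return events, xmax * 1000.0 if xmax is not None else None


def _read_events_midi(path: Path) -> tuple[list[PitchEvent], float | None]:
    from ._midi import read_midi_notes

    notes = read_midi_notes(path)  # (onset_ms, duration_ms, note_number)
    events = []
    last_offset = 0.0
    for onset_ms, duration_ms, note in notes:
        if onset_ms < last_offset - 1e-9:
            raise MonophonicityError(
                f"{path.name}: note at {onset_ms:.1f} ms overlaps previous note"
            )
        events.append(
            PitchEvent(onset=onset_ms, duration=duration_ms, pitch=midi_note_to_hz(note))
        )
        last_offset = onset_ms + duration_ms
    return events, None


# ---------------------------------------------------------------------------
# Keypress logs
# ---------------------------------------------------------------------------

_KEYPRESS_COLUMNS = [
    "participant_id",
    "instruction",
    "stimulus_id",
    "version",
    "press_ms",
    "baseline_rt_ms",
]


def read_keypress_csv(path: str | Path, *, grace_ms: float = DEFAULT_GRACE_MS) -> list[KeyPressLog]:
    """Read keypress logs (one row per press; empty ``press_ms`` registers a
    participant x stimulus cell with zero presses)."""
    df = pd.read_csv(path)
    missing = set(_KEYPRESS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {sorted(missing)}")
    logs = []
    keys = ["participant_id", "instruction", "stimulus_id", "version"]
    for (pid, instr, stim, ver), grp in df.groupby(keys, sort=False):
        presses = sorted(float(t) for t in grp["press_ms"].dropna())
        baseline = float(grp["baseline_rt_ms"].iloc[0])
        logs.append(
            KeyPressLog(
                participant_id=str(pid),
                instruction=instr,
                stimulus_id=str(stim),
                version=ver,
                press_times=tuple(presses),
                baseline_rt=baseline,
                grace_ms=grace_ms,
            )
        )
    return logs


def write_keypress_csv(logs: Iterable[KeyPressLog], path: str | Path) -> None:
    rows = []
    for log in logs:
        if log.press_times:
            for t in log.press_times:
                rows.append(
                    (log.participant_id, log.instruction, log.stimulus_id, log.version, t, log.baseline_rt)
                )
        else:
            rows.append(
                (log.participant_id, log.instruction, log.stimulus_id, log.version, None, log.baseline_rt)
            )
    pd.DataFrame(rows, columns=_KEYPRESS_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a long-format result table as CSV or JSON (records orient)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=1))
    else:
        raise ParseError(f"unknown results format {format!r}")


def read_results(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ParseError(f"unknown results format {format!r}")
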