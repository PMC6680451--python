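"""Rule-based detection of virtual segmentation points under seven boundary-cue
models, and their assembly into a disjoint model set.

The seven models
----------------
Two local cues, ``pause`` (silence longer than a threshold; the silence onset
is the segmentation point) and ``pitch_break`` (a large pitch contrast across
a short silence; the onset of the second pitch is the point); two global cues,
``pitch_rise`` and ``pitch_drop`` (sustained unidirectional pitch movements;
the movement offset is the point); and three combinations in which a pause
coexists with a break, rise or drop (``pause_pitch_break``,
``pause_pitch_rise``, ``pause_pitch_drop``; the pause onset is the point).

A movement qualifies either by pitch span (at least a fixed fraction of the
stimulus' global pitch range) or by duration; drops must additionally end in
a low-frequency region relative to the stimulus mean.  Short
counter-directional deflections and short internal silences are tolerated
inside a movement.  Candidates that end up sharing a timestamp are resolved
by a fixed precedence (richer evidence wins), so the seven model lists are
pairwise disjoint in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, ParseError
from .events import PitchStream, StimulusStats, stimulus_stats

__all__ = [
    "MODELS",
    "CuePoint",
    "CueModelSet",
    "CueThresholds",
    "detect_pauses",
    "detect_pitch_breaks",
    "detect_pitch_movements",
    "assemble_model_set",
    "global_array_diagnostics",
    "write_cues_csv",
    "read_cues_csv",
]

#: The seven cue models, in canonical (reporting) order.
MODELS = (
    "pause",
    "pitch_break",
    "pause_pitch_break",
    "pitch_rise",
    "pitch_drop",
    "pause_pitch_rise",
    "pause_pitch_drop",
)

# Higher wins when several candidates share one timestamp.
_PRECEDENCE = {
    "pause_pitch_rise": 6,
    "pause_pitch_drop": 6,
    "pause_pitch_break": 5,
    "pitch_rise": 4,
    "pitch_drop": 4,
    "pitch_break": 3,
    "pause": 2,
}

_TIME_EPS = 1e-6  # ms; tolerance when comparing candidate timestamps


@dataclass(frozen=True)
class CueThresholds:
    """Detection thresholds; defaults are the published rule set."""

    pause_min_ms: float = 200.0
    break_gap_max_ms: float = 200.0
    break_delta_sd: float = 1.0
    movement_range_fraction: float = 1.0 / 3.0
    rise_min_ms: float = 500.0
    drop_min_ms: float = 1000.0
    drop_low_end_sd: float = 0.5
    deflection_max_ms_rise: float = 250.0
    deflection_max_ms_drop: float = 200.0
    within_movement_pause_max_ms: float = 200.0
    movement_min_events: int = 2

    def __post_init__(self) -> None:
        for name in (
            "pause_min_ms",
            "break_gap_max_ms",
            "break_delta_sd",
            "movement_range_fraction",
            "rise_min_ms",
            "drop_min_ms",
            "drop_low_end_sd",
            "deflection_max_ms_rise",
            "deflection_max_ms_drop",
            "within_movement_pause_max_ms",
            "movement_min_events",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class CuePoint:
    """One virtual segmentation point with its supporting evidence span."""

    time: float
    model: str
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"unknown cue model {self.model!r}")


@dataclass(frozen=True)
class CueModelSet:
    """The seven disjoint cue-point lists for one stimulus version, plus the
    merged global time array."""

    stimulus_id: str
    version: str
    points_by_model: dict[str, tuple[CuePoint, ...]]
    global_array: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "global_array", np.asarray(self.global_array, dtype=float))

    def all_points(self) -> list[CuePoint]:
        return sorted(
            (p for pts in self.points_by_model.values() for p in pts),
            key=lambda p: p.time,
        )

    def model_of_time(self) -> dict[float, str]:
        return {p.time: p.model for p in self.all_points()}


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_pauses(
    stream: PitchStream, thresholds: CueThresholds | None = None
) -> list[tuple[float, float]]:
    """Silent spans strictly longer than ``pause_min_ms``.

    Returns ``(pause_onset, pause_offset)`` pairs; the pause onset (= previous
    event offset) is the candidate segmentation point.
    """
    th = thresholds or CueThresholds()
    return [
        (start, end)
        for start, end in stream.gaps()
        if (end - start) > th.pause_min_ms
    ]


def detect_pitch_breaks(
    stream: PitchStream,
    stats: StimulusStats | None = None,
    thresholds: CueThresholds | None = None,
) -> list[CuePoint]:
    """Pitch contrasts larger than ``break_delta_sd`` standard deviations
    between consecutive events separated by a silence.

    A contrast across a silence shorter than ``break_gap_max_ms`` yields a
    ``pitch_break`` at the onset of the second event; the same contrast across
    a pause (silence longer than ``pause_min_ms``) yields a
    ``pause_pitch_break`` at the pause onset.  Abutting events (no silence)
    yield nothing, and contrasts of exactly the threshold are excluded
    (strict inequality).
    """
    th = thresholds or CueThresholds()
    st = stats or stimulus_stats(stream)
    out: list[CuePoint] = []
    for a, b in zip(stream.events, stream.events[1:]):
        gap = b.onset - a.offset
        if gap <= 0:
            continue  # no silence, no break
        if abs(b.pitch - a.pitch) <= th.break_delta_sd * st.sd_pitch_hz:
            continue
        if gap < th.break_gap_max_ms:
            out.append(CuePoint(time=b.onset, model="pitch_break", extent=(a.offset, b.onset)))
        elif gap > th.pause_min_ms:
            out.append(
                CuePoint(time=a.offset, model="pause_pitch_break", extent=(a.offset, b.onset))
            )
    return out


def _movement_runs(
    stream: PitchStream, direction: int, th: CueThresholds
) -> list[tuple[int, int]]:
    """Maximal event-index runs moving monotonically in ``direction``.

    A run starts on a directional step and extends while internal silences
    stay within ``within_movement_pause_max_ms`` and counter-directional
    deflections resolve within the direction's deflection allowance.  Runs
    strictly contained in an earlier (longer) run are suppressed.
    """
    ev = stream.events
    n = len(ev)
    defl_max = (
        th.deflection_max_ms_rise if direction > 0 else th.deflection_max_ms_drop
    )
    runs: list[tuple[int, int]] = []
    max_end = -1
    for start in range(n - 1):
        if direction * (ev[start + 1].pitch - ev[start].pitch) <= 0:
            continue  # a run must open with a directional step
        last_good = start
        defl_start: float | None = None
        k = start
        while k < n - 1:
            gap = ev[k + 1].onset - ev[k].offset
            if gap > th.within_movement_pause_max_ms:
                break
            delta = ev[k + 1].pitch - ev[k].pitch
            if direction * delta > 0:
                if defl_start is not None:
                    if ev[k + 1].onset - defl_start > defl_max:
                        break
                    defl_start = None
                last_good = k + 1
            else:
                if defl_start is None:
                    defl_start = ev[k + 1].onset
                elif ev[k + 1].onset - defl_start > defl_max:
                    break  # deflection already too long to ever resolve
            k += 1
        if last_good > start and last_good > max_end:
            runs.append((start, last_good))
            max_end = last_good
    return runs


def detect_pitch_movements(
    stream: PitchStream,
    stats: StimulusStats | None = None,
    thresholds: CueThresholds | None = None,
    direction: Literal["rise", "drop"] = "rise",
) -> list[CuePoint]:
    """Qualifying unidirectional pitch movements; the movement offset is the
    candidate segmentation point.

    A run qualifies if its pitch span reaches ``movement_range_fraction`` of
    the global pitch range, or if it lasts at least ``rise_min_ms`` /
    ``drop_min_ms``.  Drops must additionally end at or below
    ``mean - drop_low_end_sd * sd`` regardless of which disjunct qualified
    them.
    """
    if direction not in ("rise", "drop"):
        raise ConfigError(f"direction must be 'rise' or 'drop', got {direction!r}")
    th = thresholds or CueThresholds()
    st = stats or stimulus_stats(stream)
    sign = 1 if direction == "rise" else -1
    min_dur = th.rise_min_ms if direction == "rise" else th.drop_min_ms
    model = "pitch_rise" if direction == "rise" else "pitch_drop"
    ev = stream.events
    out: list[CuePoint] = []
    for s, e in _movement_runs(stream, sign, th):
        if e - s + 1 < th.movement_min_events:
            continue
        span = sign * (ev[e].pitch - ev[s].pitch)
        duration = ev[e].offset - ev[s].onset
        if not (
            span >= th.movement_range_fraction * st.pitch_range_hz or duration >= min_dur
        ):
            continue
        if direction == "drop" and ev[e].pitch > (
            st.mean_pitch_hz - th.drop_low_end_sd * st.sd_pitch_hz
        ):
            continue
        out.append(CuePoint(time=ev[e].offset, model=model, extent=(ev[s].onset, ev[e].offset)))
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_model_set(
    stream: PitchStream,
    stats: StimulusStats | None = None,
    thresholds: CueThresholds | None = None,
) -> CueModelSet:
    """Run all detectors and assign every candidate to exactly one model.

    A movement whose offset coincides with a pause onset becomes
    ``pause_pitch_rise`` / ``pause_pitch_drop`` (point at the pause onset).
    When several candidates share one timestamp the model with the richest
    evidence wins (pause+movement > pause+break > movement > break > pause);
    the global array is the sorted deduplicated union of the surviving times.
    """
    th = thresholds or CueThresholds()
    st = stats or stimulus_stats(stream)

    pauses = detect_pauses(stream, th)
    pause_by_onset = {round(p[0], 6): p for p in pauses}
    candidates: list[CuePoint] = [
        CuePoint(time=start, model="pause", extent=(start, end)) for start, end in pauses
    ]
    candidates += detect_pitch_breaks(stream, st, th)
    for direction in ("rise", "drop"):
        for cand in detect_pitch_movements(stream, st, th, direction):
            pause = pause_by_onset.get(round(cand.time, 6))
            if pause is not None:
                candidates.append(
                    CuePoint(
                        time=pause[0],
                        model=f"pause_{cand.model}",
                        extent=(cand.extent[0], pause[1]),
                    )
                )
            else:
                candidates.append(cand)

    # exclusive assignment: one model per timestamp, by precedence
    by_time: dict[float, CuePoint] = {}
    for cand in sorted(candidates, key=lambda c: (round(c.time, 6), _PRECEDENCE[c.model])):
        by_time[round(cand.time, 6)] = cand  # higher precedence overwrites

    points_by_model: dict[str, list[CuePoint]] = {m: [] for m in MODELS}
    for cand in by_time.values():
        points_by_model[cand.model].append(cand)
    for m in MODELS:
        points_by_model[m].sort(key=lambda p: p.time)

    global_array = np.array(sorted(by_time.keys()), dtype=float)
    return CueModelSet(
        stimulus_id=stream.stimulus_id,
        version=stream.version,
        points_by_model={m: tuple(v) for m, v in points_by_model.items()},
        global_array=global_array,
    )


def global_array_diagnostics(model_set: CueModelSet) -> tuple[int, float]:
    """``(n_points, max_adjacent_gap_ms)`` of the merged global array."""
    times = model_set.global_array
    if times.size == 0:
        raise InsufficientDataError("global array is empty")
    if times.size == 1:
        return 1, 0.0
    return int(times.size), float(np.diff(times).max())


# ---------------------------------------------------------------------------
# Cue CSV exchange (schema: time_ms,model,extent_start_ms,extent_end_ms)
# ---------------------------------------------------------------------------

def write_cues_csv(model_set: CueModelSet, path: str | Path) -> None:
    rows = [
        {
            "stimulus_id": model_set.stimulus_id,
            "version": model_set.version,
            "time_ms": p.time,
            "model": p.model,
            "extent_start_ms": p.extent[0],
            "extent_end_ms": p.extent[1],
        }
        for p in model_set.all_points()
    ]
    pd.DataFrame(
        rows,
        columns=[
            "stimulus_id",
            "version",
            "time_ms",
            "model",
            "extent_start_ms",
            "extent_end_ms",
        ],
    ).to_csv(path, index=False)


def read_cues_csv(path: str | Path) -> list[CueModelSet]:
    df = pd.read_csv(path)
    required = {"stimulus_id", "version", "time_ms", "model"}
    if not required.issubset(df.columns):
        raise ParseError(f"{Path(path).name}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for (stim, ver), grp in df.groupby(["stimulus_id", "version"], sort=False):
        points: dict[str, list[CuePoint]] = {m: [] for m in MODELS}
        for row in grp.itertuples(index=False):
            extent = (
                float(getattr(row, "extent_start_ms", row.time_ms)),
                float(getattr(row, "extent_end_ms", row.time_ms)),
            )
            points[row.model].append(CuePoint(time=float(row.time_ms), model=row.model, extent=extent))
        for m in MODELS:
            points[m].sort(key=lambda p: p.time)
        times = sorted({round(p.time, 6) for pts in points.values() for p in pts})
        out.append(
            CueModelSet(
                stimulus_id=str(stim),
                version=str(ver),
                points_by_model={m: tuple(v) for m, v in points.items()},
                global_array=np.array(times, dtype=float),
            )
        )
    return out
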