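"""Synthetic stimuli and simulated keypress responders.

The generator produces ~60 s utterance-like pitch contours organised as a
phrase plan: stretches of plateau "syllables" (stable-pitch events on a
12-TET semitone grid, ~3.9 events/s) separated by planted boundary cues, one
of the seven detector models per internal phrase boundary.  Ground truth
records each planted cue's model and segmentation time.

In the default *clean* mode the template is built so that the detectors
recover exactly the planted cues and nothing else: outside planted
movements, consecutive pitch steps never share a sign (so monotone runs have
two events and stay under the movement duration thresholds), every
non-break step stays well under one standard deviation of the stimulus
pitch, unplanted descents end far above the drop low-frequency region, and
all silences are well clear of the pause threshold.  These margins are
verified numerically against the *realised* stimulus statistics after
generation, with a bounded, seeded retry when a random draw lands too close
to a threshold.

Realism knobs (pitch jitter in cents, declination, pause-length jitter)
produce off-grid contours emulating natural speech; with them enabled, exact
recovery is no longer guaranteed (that is the point).

Responders press around cue times with a participant-specific latency (their
measured baseline RT), hit probabilities per cue model, Poisson false
alarms, motor jitter and a refractory period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cues import MODELS, CueModelSet, CueThresholds, assemble_model_set
from .errors import ConfigError
from .events import KeyPressLog, PitchEvent, PitchStream, stimulus_stats

__all__ = [
    "PhraseSpec",
    "StimulusConfig",
    "ResponderConfig",
    "ExperimentConfig",
    "PlantedCue",
    "Contour",
    "ExperimentData",
    "generate_contour",
    "delexicalize",
    "naturalize",
    "quantize_to_semitone",
    "simulate_responders",
    "simulate_experiment",
]

# Template constants.  Syllable + intra-phrase gap = 260 ms, which exceeds
# both deflection allowances (250/200 ms), so a single counter-directional or
# flat event always terminates a detector run; and a two-event monotone run
# lasts 490 ms, under the 500 ms rise-duration threshold.
_SYLLABLE_MS = 230.0
_GAP_MS = 30.0
_STEP_MS = _SYLLABLE_MS + _GAP_MS
_PAUSE_GAP_MS = 400.0
# breaks use the ordinary inter-syllable gap: the pitch contrast, not the
# silence, carries the cue, and the two-event jump chain must stay under the
# 500 ms rise-duration threshold (230 + 30 + 230 = 490 ms)
_BREAK_GAP_MS = _GAP_MS
_RISE_STEPS = 5  # +1 semitone each, above the plateau anchor
_RISE_PEAK_MIN = 9  # semitones; keeps the global range wide
_PLATEAU_MAX = 3
_DROP_BOTTOM = -7  # semitones relative to the base note
_BREAK_JUMP = 4  # semitones, upward
_MARGIN = 1.08  # multiplicative safety margin for threshold checks


@dataclass(frozen=True)
class PhraseSpec:
    """One phrase of the plan; ``boundary`` is the cue model planted at its
    end (``None`` for the final phrase)."""

    length_ms: float
    boundary: str | None

    def __post_init__(self) -> None:
        if self.boundary is not None and self.boundary not in MODELS:
            raise ConfigError(f"unknown boundary cue {self.boundary!r}")
        if self.length_ms <= 0:
            raise ConfigError("phrase length must be positive")


@dataclass(frozen=True)
class StimulusConfig:
    stimulus_id: str = "s1"
    duration_s: float = 60.0
    base_midi_note: int = 48  # C3 ~ 130.8 Hz; governs mean pitch
    phrase_plan: tuple[PhraseSpec, ...] | None = None
    syllable_ms: float = _SYLLABLE_MS
    gap_ms: float = _GAP_MS
    jitter_cents: float = 0.0  # per-event pitch jitter (off-grid; realism)
    declination_st_per_s: float = 0.0  # slow downward drift (realism)
    pause_jitter_ms: float = 0.0  # boundary-gap jitter (realism)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.syllable_ms <= 0 or self.gap_ms < 0:
            raise ConfigError("durations must be positive")

    @property
    def clean(self) -> bool:
        return (
            self.jitter_cents == 0
            and self.declination_st_per_s == 0
            and self.pause_jitter_ms == 0
        )


@dataclass(frozen=True)
class PlantedCue:
    time: float
    model: str
    extent: tuple[float, float]


@dataclass(frozen=True)
class Contour:
    """Dense pitch track (NaN in silences) plus syllable spans and ground truth."""

    times: np.ndarray = field(repr=False)
    f0: np.ndarray = field(repr=False)
    syllables: tuple[tuple[float, float], ...]
    truth: tuple[PlantedCue, ...]
    total_duration: float
    config: StimulusConfig


def _semitone_to_hz(base_midi: float, level: float) -> float:
    return 440.0 * 2.0 ** ((base_midi + level - 69) / 12.0)


def quantize_to_semitone(f_hz: float) -> float:
    """Snap a frequency to the nearest 12-TET semitone (A4 = 440 Hz)."""
    if f_hz <= 0:
        raise ConfigError("frequency must be positive")
    note = round(69 + 12 * math.log2(f_hz / 440.0))
    return 440.0 * 2.0 ** ((note - 69) / 12.0)


# ---------------------------------------------------------------------------
# Phrase-plan assembly (semitone-level event sequences)
# ---------------------------------------------------------------------------

def _default_plan(rng: np.random.Generator, duration_s: float) -> tuple[PhraseSpec, ...]:
    """Fourteen phrases whose thirteen internal boundaries cover all seven
    models (the short-motif cues appear twice or thrice)."""
    boundaries = list(MODELS) + [
        "pause",
        "pitch_break",
        "pitch_rise",
        "pause",
        "pitch_break",
        "pause_pitch_rise",
    ]
    rng.shuffle(boundaries)
    # movement phrases need room for their motifs (and following recoveries)
    weight = {"pitch_drop": 1.7, "pause_pitch_drop": 1.5, "pitch_rise": 1.3}
    weights = [weight.get(b, 1.0) for b in boundaries] + [1.0]
    # reserve ~8% for motif extensions so the realised length lands near target
    scale = duration_s * 1000.0 * 0.92 / sum(weights)
    specs = [
        PhraseSpec(length_ms=w * scale, boundary=b)
        for b, w in zip(boundaries + [None], weights)  # type: ignore[list-item]
    ]
    return tuple(specs)


def _zigzag(level: int, n: int, start_up: bool) -> list[int]:
    """Alternating plateau levels; never two consecutive same-sign steps."""
    return [level + 1 if (i % 2 == 0) == start_up else level for i in range(n)]


def _build_levels(
    plan: Sequence[PhraseSpec], rng: np.random.Generator
) -> tuple[list[tuple[int, float]], list[tuple[int, str]]]:
    """Assemble the stimulus as ``(semitone_level, gap_after_ms)`` events plus
    ``(event_index, model)`` ground-truth markers.

    For pause-type cues the marker index is the event before the pause (the
    point is its offset); for plain breaks it is the jump-landing event (the
    point is its onset); for plain movements it is the run's final event.
    """
    levels: list[tuple[int, float]] = []
    markers: list[tuple[int, str]] = []
    preamble: list[int] = []  # levels that must open the next phrase
    prev_boundary: str | None = None

    for phrase in plan:
        boundary = phrase.boundary
        start_at_plateau = False
        # the break jump must start low enough that its span stays under a
        # third of the global range
        cap = 2 if boundary in ("pitch_break", "pause_pitch_break") else _PLATEAU_MAX
        if preamble:
            plateau = preamble[-1]
            if plateau > cap:  # continue the straight descent a little lower
                preamble = preamble + list(range(plateau - 1, cap - 1, -1))
                plateau = cap
        elif prev_boundary == "pause" and levels:
            # the contrast across a plain pause must stay within one semitone
            last_lvl = levels[-1][0]
            plateau = int(np.clip(last_lvl + rng.integers(-1, 2), 0, cap))
            start_at_plateau = True
        else:
            plateau = int(rng.integers(0, cap + 1))

        body: list[int] = list(preamble)
        preamble = []

        if boundary in ("pitch_rise", "pause_pitch_rise"):
            # the peak also anchors the global pitch range (jump-span margin)
            peak = max(plateau + _RISE_STEPS, _RISE_PEAK_MIN)
            motif = list(range(plateau + 1, peak + 1))
        elif boundary in ("pitch_drop", "pause_pitch_drop"):
            motif = list(range(plateau, _DROP_BOTTOM - 1, -1))
        else:
            motif = []

        n_total = max(len(body) + len(motif) + 2, int(round(phrase.length_ms / _STEP_MS)))
        n_fill = n_total - len(body) - len(motif)
        if start_at_plateau:
            start_up = False  # first event exactly at the plateau
        else:
            start_up = not (body and body[-1] == plateau + 1)
        body += _zigzag(plateau, n_fill, start_up=start_up)
        if boundary in ("pitch_break", "pause_pitch_break") and body[-1] != plateau:
            body.append(plateau)  # jump chain must be exactly two events
        body += motif

        for lvl in body:
            levels.append((lvl, _GAP_MS))
        last = len(levels) - 1
        prev_boundary = boundary

        if boundary is None:
            continue
        if boundary == "pause":
            levels[last] = (levels[last][0], _PAUSE_GAP_MS)
            markers.append((last, "pause"))
        elif boundary in ("pitch_break", "pause_pitch_break"):
            gap = _BREAK_GAP_MS if boundary == "pitch_break" else _PAUSE_GAP_MS
            levels[last] = (levels[last][0], gap)
            target = levels[last][0] + _BREAK_JUMP
            # long straight descents must land above the drop low-end region
            nxt = int(rng.integers(2, 4))
            preamble = [target] + list(range(target - 1, nxt - 1, -1))
            if boundary == "pitch_break":
                markers.append((last + 1, "pitch_break"))  # landing event
            else:
                markers.append((last, "pause_pitch_break"))
        elif boundary == "pitch_rise":
            markers.append((last, "pitch_rise"))
            peak = levels[last][0]
            nxt = int(rng.integers(2, 4))
            preamble = list(range(peak - 1, nxt - 1, -1)) or [nxt]
        elif boundary == "pause_pitch_rise":
            levels[last] = (levels[last][0], _PAUSE_GAP_MS)
            markers.append((last, "pause_pitch_rise"))
        elif boundary == "pitch_drop":
            markers.append((last, "pitch_drop"))
            nxt = int(rng.integers(0, 3))
            recovery: list[int] = []
            lvl = _DROP_BOTTOM
            while lvl < nxt:
                lvl = min(nxt, lvl + (2 if lvl < -2 else 1))
                recovery += [lvl, lvl]  # ascend then flat: runs stay two events
            preamble = recovery or [nxt]
        elif boundary == "pause_pitch_drop":
            levels[last] = (levels[last][0], _PAUSE_GAP_MS)
            markers.append((last, "pause_pitch_drop"))
    return levels, sorted(markers)


def generate_contour(config: StimulusConfig) -> Contour:
    """Generate a dense pitch contour with planted boundary cues.

    In clean mode the realised margins are verified against the detector
    thresholds; a draw that lands too close to a threshold is regenerated
    from the next child seed (bounded, deterministic).
    """
    seed_seq = np.random.SeedSequence(config.seed)
    last_err: Exception | None = None
    for child in seed_seq.spawn(50):
        rng = np.random.default_rng(child)
        plan = config.phrase_plan or _default_plan(rng, config.duration_s)
        levels, markers = _build_levels(plan, rng)
        contour = _render(config, levels, markers, rng)
        if not config.clean:
            return contour
        try:
            _validate_clean(contour, markers, levels)
            return contour
        except _MarginViolation as exc:
            last_err = exc
    raise ConfigError(f"could not realise a clean stimulus: {last_err}")


class _MarginViolation(Exception):
    pass


def _render(
    config: StimulusConfig,
    levels: list[tuple[int, float]],
    markers: list[tuple[int, str]],
    rng: np.random.Generator,
) -> Contour:
    base = config.base_midi_note
    syl = config.syllable_ms
    onsets, durations = [], []
    t = 0.0
    for _, gap in levels:
        onsets.append(t)
        durations.append(syl)
        jitter = 0.0
        if gap > config.gap_ms and config.pause_jitter_ms > 0:
            jitter = float(rng.normal(0, config.pause_jitter_ms))
        t += syl + max(gap + jitter, 1.0)
    total = onsets[-1] + durations[-1] + 400.0  # trailing silence

    st = np.array([lvl for lvl, _ in levels], dtype=float)
    if config.declination_st_per_s:
        st = st - config.declination_st_per_s * (np.asarray(onsets) / 1000.0)
    if config.jitter_cents:
        st = st + rng.normal(0, config.jitter_cents / 100.0, size=st.size)
    hz = np.array([_semitone_to_hz(base, s) for s in st])

    step = 5.0
    times = np.arange(0.0, total, step)
    f0 = np.full_like(times, np.nan)
    for onset, dur, f in zip(onsets, durations, hz):
        sel = (times >= onset) & (times < onset + dur)
        f0[sel] = f
    syllables = tuple((o, o + d) for o, d in zip(onsets, durations))

    truth = []
    for idx, model in markers:
        if model == "pitch_break":
            time = onsets[idx]
            extent = (onsets[idx - 1] + durations[idx - 1], time)
        elif model.startswith("pause"):
            time = onsets[idx] + durations[idx]
            end = onsets[idx + 1] if idx + 1 < len(onsets) else total
            extent = (time, end)
        else:  # pitch_rise / pitch_drop: the movement offset
            time = onsets[idx] + durations[idx]
            extent = (time, time)
        truth.append(PlantedCue(time=time, model=model, extent=extent))
    truth.sort(key=lambda c: c.time)
    return Contour(
        times=times,
        f0=f0,
        syllables=syllables,
        truth=tuple(truth),
        total_duration=total,
        config=config,
    )


def _monotone_chains(events, pause_min: float) -> list[tuple[int, int, int]]:
    """Maximal strictly-monotone index chains ``(first, last, sign)`` over
    steps whose silences could sit inside a detector run (gap <= pause_min).

    Because every event (with its gap) lasts longer than both deflection
    allowances, detector movement runs coincide exactly with these chains in
    clean-template streams.
    """
    chains = []
    i = 0
    n = len(events)
    while i < n - 1:
        gap = events[i + 1].onset - events[i].offset
        delta = events[i + 1].pitch - events[i].pitch
        if gap > pause_min or delta == 0:
            i += 1
            continue
        sign = 1 if delta > 0 else -1
        j = i + 1
        while j < n - 1:
            gap = events[j + 1].onset - events[j].offset
            delta = events[j + 1].pitch - events[j].pitch
            if gap > pause_min or sign * delta <= 0:
                break
            j += 1
        chains.append((i, j, sign))
        i = j
    return chains


def _validate_clean(contour: Contour, markers, levels) -> None:
    """Numeric margin checks: the realised stimulus statistics must keep every
    planted cue strictly on its side of the detector thresholds (with slack),
    and nothing unplanted may come close to qualifying."""
    stream = naturalize(contour)
    st = stimulus_stats(stream)
    th = CueThresholds()
    sd = st.sd_pitch_hz
    range3 = st.pitch_range_hz * th.movement_range_fraction
    low_end = st.mean_pitch_hz - th.drop_low_end_sd * sd
    ev = stream.events

    if contour.config.syllable_ms + contour.config.gap_ms <= max(
        th.deflection_max_ms_rise, th.deflection_max_ms_drop
    ):
        raise _MarginViolation("event grid too fast for single-event deflection breaking")

    break_landings = {i for i, m in markers if m == "pitch_break"}
    pause_break_left = {i for i, m in markers if m == "pause_pitch_break"}
    movement_pause_left = {
        i for i, m in markers if m in ("pause_pitch_rise", "pause_pitch_drop")
    }
    pause_like_left = {i for i, m in markers if m.startswith("pause")}
    rise_final = {i for i, m in markers if m in ("pitch_rise", "pause_pitch_rise")}
    drop_final = {i for i, m in markers if m in ("pitch_drop", "pause_pitch_drop")}

    # pairwise contrasts (break rule) and silences (pause rule)
    for i in range(len(ev) - 1):
        gap = ev[i + 1].onset - ev[i].offset
        delta = abs(ev[i + 1].pitch - ev[i].pitch)
        if i in pause_like_left:
            if gap <= th.pause_min_ms * _MARGIN:
                raise _MarginViolation("planted pause too short")
        elif gap > th.pause_min_ms / _MARGIN:
            raise _MarginViolation("unplanted silence rivals the pause threshold")
        if (i + 1) in break_landings or i in pause_break_left:
            if delta <= _MARGIN * th.break_delta_sd * sd:
                raise _MarginViolation(
                    f"planted break contrast {delta:.1f} Hz too small (sd {sd:.1f})"
                )
        elif i in movement_pause_left:
            pass  # large contrast coincides with the movement point; precedence wins
        elif gap > 0 and delta >= th.break_delta_sd * sd / _MARGIN:
            raise _MarginViolation(
                f"unplanted step of {delta:.1f} Hz too close to the break threshold "
                f"(sd {sd:.1f}) at {ev[i].offset:.0f} ms"
            )

    # movement runs
    for first, final, sign in _monotone_chains(ev, th.pause_min_ms):
        span = abs(ev[final].pitch - ev[first].pitch)
        duration = ev[final].offset - ev[first].onset
        if sign > 0:
            if final in rise_final:
                if duration <= th.rise_min_ms * _MARGIN:
                    raise _MarginViolation("planted rise too brief")
                continue
            if duration >= th.rise_min_ms or span >= range3 / _MARGIN:
                raise _MarginViolation(
                    f"unplanted ascent would qualify as a rise at {ev[final].offset:.0f} ms"
                )
        else:
            if final in drop_final:
                if duration <= th.drop_min_ms * _MARGIN:
                    raise _MarginViolation("planted drop too brief")
                if ev[final].pitch > low_end - 0.15 * sd:
                    raise _MarginViolation("planted drop does not reach the low range")
                continue
            qualifies = duration >= th.drop_min_ms or span >= range3 / _MARGIN
            if qualifies and ev[final].pitch <= low_end + 0.15 * sd:
                raise _MarginViolation(
                    f"unplanted descent would qualify as a drop at {ev[final].offset:.0f} ms"
                )

    # plain movements must not abut a pause; pause-movements must
    for i, m in markers:
        gap = (ev[i + 1].onset - ev[i].offset) if i + 1 < len(ev) else math.inf
        if m in ("pitch_rise", "pitch_drop") and gap > th.pause_min_ms:
            raise _MarginViolation("plain movement abuts a pause")

    if not (105.0 <= st.mean_pitch_hz <= 195.0):
        raise _MarginViolation(f"mean pitch {st.mean_pitch_hz:.1f} Hz outside the speech band")


# ---------------------------------------------------------------------------
# Contour -> PitchStream (the two stimulus versions)
# ---------------------------------------------------------------------------

def _segment(contour: Contour, quantize: bool) -> PitchStream:
    events = []
    for start, end in contour.syllables:
        sel = (contour.times >= start) & (contour.times < end) & ~np.isnan(contour.f0)
        if not sel.any():
            continue
        pitch = float(contour.f0[sel].mean())
        if quantize:
            pitch = quantize_to_semitone(pitch)
        events.append(PitchEvent(onset=start, duration=end - start, pitch=pitch))
    return PitchStream(
        stimulus_id=contour.config.stimulus_id,
        version="delexicalized" if quantize else "natural",
        events=tuple(events),
        total_duration=contour.total_duration,
    )


def delexicalize(contour: Contour) -> PitchStream:
    """Segment the contour at syllable onsets into stable-pitch events, each
    snapped to the nearest 12-TET semitone (the audio-to-MIDI emulation)."""
    return _segment(contour, quantize=True)


def naturalize(contour: Contour) -> PitchStream:
    """Same segmentation, event pitch = contour mean over the span (no grid)."""
    return _segment(contour, quantize=False)


# ---------------------------------------------------------------------------
# Responders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponderConfig:
    instruction: str = "speech"
    cue_weights: dict = field(default_factory=lambda: {m: 0.7 for m in MODELS})
    false_alarm_rate: float = 0.0  # events per minute
    rt_mean_ms: float = 287.0
    rt_sd_ms: float = 50.0
    motor_jitter_sd_ms: float = 0.0
    refractory_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instruction not in ("speech", "music"):
            raise ConfigError(f"unknown instruction {self.instruction!r}")
        for m, w in self.cue_weights.items():
            if m not in MODELS or not 0.0 <= w <= 1.0:
                raise ConfigError(f"bad cue weight {m}={w}")
        if self.rt_mean_ms <= 0 or self.rt_sd_ms < 0:
            raise ConfigError("RT parameters must be positive")
        if self.false_alarm_rate < 0:
            raise ConfigError("false_alarm_rate must be >= 0")


def _draw_baseline_rt(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        rt = float(rng.normal(mean, sd))
        if rt > 0:
            return rt
    return max(mean, 1.0)


def simulate_responders(
    model_set: CueModelSet,
    config: ResponderConfig,
    n_participants: int,
    *,
    total_duration: float,
    participant_ids: Sequence[str] | None = None,
    baseline_rts: Sequence[float] | None = None,
) -> list[KeyPressLog]:
    """Simulate keypress logs for one stimulus version.

    Each cue of model M elicits a press with probability ``cue_weights[M]``
    at the cue time plus the participant's baseline RT plus motor jitter;
    false alarms arrive as a Poisson process over the stimulus.  Presses
    within ``refractory_ms`` of the previous kept press are collapsed.  Pass
    ``baseline_rts``/``participant_ids`` to reuse participants across stimuli.
    """
    if model_set.global_array.size == 0:
        raise ConfigError("cannot simulate responders on an empty global array")
    if all(w == 0 for w in config.cue_weights.values()) and config.false_alarm_rate == 0:
        warnings.warn("all cue weights and the false-alarm rate are zero: empty logs")
    rng = np.random.default_rng(config.seed)
    logs = []
    for i in range(n_participants):
        pid = participant_ids[i] if participant_ids else f"{config.instruction}{i + 1:03d}"
        if baseline_rts is not None:
            baseline = float(baseline_rts[i])
        else:
            baseline = _draw_baseline_rt(rng, config.rt_mean_ms, config.rt_sd_ms)
        presses = []
        for model in MODELS:
            w = config.cue_weights.get(model, 0.0)
            for point in model_set.points_by_model[model]:
                if rng.random() < w:
                    t = point.time + baseline
                    if config.motor_jitter_sd_ms > 0:
                        t += float(rng.normal(0, config.motor_jitter_sd_ms))
                    presses.append(t)
        if config.false_alarm_rate > 0:
            n_fa = rng.poisson(config.false_alarm_rate * total_duration / 60000.0)
            presses.extend(rng.uniform(0.0, total_duration, size=int(n_fa)).tolist())
        presses = sorted(max(t, 1.0) for t in presses)
        kept: list[float] = []
        for t in presses:
            if kept and t - kept[-1] <= max(config.refractory_ms, 1e-6):
                continue
            kept.append(t)
        logs.append(
            KeyPressLog(
                participant_id=pid,
                instruction=config.instruction,  # type: ignore[arg-type]
                stimulus_id=model_set.stimulus_id,
                version=model_set.version,  # type: ignore[arg-type]
                press_times=tuple(kept),
                baseline_rt=baseline,
                total_duration=total_duration,
            )
        )
    return logs


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """The two-group design: instruction (between) x version (within) x
    stimuli; the delexicalization x instruction interaction is planted through
    group- and version-specific cue weights."""

    n_per_group: int = 35
    n_stimuli: int = 5
    seed: int = 0
    duration_s: float = 60.0
    # hit probabilities: (instruction, version) -> scalar, or model -> prob dict
    weights: dict = field(
        default_factory=lambda: {
            ("speech", "natural"): 0.65,
            ("speech", "delexicalized"): 0.35,
            ("music", "natural"): 0.65,
            ("music", "delexicalized"): 0.65,
        }
    )
    false_alarm_rate: float = 1.0
    rt_mean_ms: float = 287.0
    rt_sd_ms: float = 50.0
    motor_jitter_sd_ms: float = 30.0
    refractory_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("need at least 2 participants per group")
        if self.n_stimuli < 1:
            raise ConfigError("need at least one stimulus")
        for instr in ("speech", "music"):
            for version in ("natural", "delexicalized"):
                if (instr, version) not in self.weights:
                    raise ConfigError(f"weights missing cell {(instr, version)}")


@dataclass
class ExperimentData:
    config: ExperimentConfig
    streams: dict  # (stimulus_id, version) -> PitchStream
    model_sets: dict  # (stimulus_id, version) -> CueModelSet
    truths: dict  # stimulus_id -> tuple[PlantedCue, ...]
    logs: list  # KeyPressLog
    design: pd.DataFrame  # participant_id, instruction

    def instruction_map(self) -> dict:
        return dict(zip(self.design["participant_id"], self.design["instruction"]))

    def write(self, outdir) -> None:
        """Write the dataset as plain-text files (event/truth/press/design CSVs)."""
        from pathlib import Path

        from .cues import write_cues_csv
        from .events import write_events_csv, write_keypress_csv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (sid, version), stream in self.streams.items():
            write_events_csv(stream, out / f"events_{sid}_{version}.csv")
            write_cues_csv(self.model_sets[(sid, version)], out / f"cues_{sid}_{version}.csv")
        for sid, truth in self.truths.items():
            pd.DataFrame(
                [{"time_ms": c.time, "model": c.model} for c in truth]
            ).to_csv(out / f"truth_{sid}.csv", index=False)
        write_keypress_csv(self.logs, out / "presses.csv")
        self.design.to_csv(out / "design.csv", index=False)


def simulate_experiment(config: ExperimentConfig) -> ExperimentData:
    """Generate stimuli, detect cues, and simulate both participant groups on
    both stimulus versions; fully deterministic under ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    stim_seed, resp_seed, rt_seed = root.spawn(3)
    rt_rng = np.random.default_rng(rt_seed)

    streams: dict = {}
    model_sets: dict = {}
    truths: dict = {}
    base_notes = [46, 48, 50, 47, 49]
    for k, child in enumerate(stim_seed.spawn(config.n_stimuli)):
        sid = f"st{k + 1}"
        scfg = StimulusConfig(
            stimulus_id=sid,
            duration_s=config.duration_s,
            base_midi_note=base_notes[k % len(base_notes)],
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        contour = generate_contour(scfg)
        truths[sid] = contour.truth
        for version, stream in (
            ("natural", naturalize(contour)),
            ("delexicalized", delexicalize(contour)),
        ):
            streams[(sid, version)] = stream
            model_sets[(sid, version)] = assemble_model_set(stream)

    design_rows = []
    baselines = {}
    for instr in ("speech", "music"):
        for i in range(config.n_per_group):
            pid = f"{instr}{i + 1:03d}"
            design_rows.append({"participant_id": pid, "instruction": instr})
            baselines[pid] = _draw_baseline_rt(rt_rng, config.rt_mean_ms, config.rt_sd_ms)
    design = pd.DataFrame(design_rows)

    logs: list[KeyPressLog] = []
    resp_children = iter(resp_seed.spawn(2 * 2 * config.n_stimuli))
    for instr in ("speech", "music"):
        ids = [f"{instr}{i + 1:03d}" for i in range(config.n_per_group)]
        rts = [baselines[p] for p in ids]
        for version in ("natural", "delexicalized"):
            w = config.weights[(instr, version)]
            weights = dict(w) if isinstance(w, dict) else {m: float(w) for m in MODELS}
            for k in range(config.n_stimuli):
                sid = f"st{k + 1}"
                child = next(resp_children)
                rcfg = ResponderConfig(
                    instruction=instr,
                    cue_weights=weights,
                    false_alarm_rate=config.false_alarm_rate,
                    rt_mean_ms=config.rt_mean_ms,
                    rt_sd_ms=config.rt_sd_ms,
                    motor_jitter_sd_ms=config.motor_jitter_sd_ms,
                    refractory_ms=config.refractory_ms,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                logs.extend(
                    simulate_responders(
                        model_sets[(sid, version)],
                        rcfg,
                        config.n_per_group,
                        total_duration=streams[(sid, version)].total_duration,
                        participant_ids=ids,
                        baseline_rts=rts,
                    )
                )
    return ExperimentData(
        config=config,
        streams=streams,
        model_sets=model_sets,
        truths=truths,
        logs=logs,
        design=design,
    )
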