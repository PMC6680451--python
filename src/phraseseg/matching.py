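"""Keypress correction, nearest-point alignment to the global array, and
Russell-Rao model-matching scores.

A participant's raw keypress times are first corrected by subtracting their
individually measured baseline reaction time.  Each corrected press is then
snapped to the nearest time in the stimulus' global array of virtual
segmentation points, producing a binary ("logical") array over that
reference; each cue model likewise owns a logical array (1 where the model
placed a point).  The adherence of a participant to a model is the
Russell-Rao similarity ``a / n``: the number of reference positions where
both arrays are 1, over the array length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cues import MODELS, CueModelSet
from .errors import AlignmentError, ConfigError, InsufficientDataError
from .events import KeyPressLog

__all__ = [
    "LogicalArray",
    "MatchScore",
    "correct_keypresses",
    "assign_to_global",
    "model_logical_arrays",
    "russell_rao",
    "match_participant",
    "scores_to_frame",
]


@dataclass(frozen=True)
class LogicalArray:
    """A binary vector over a shared reference of global-array times."""

    reference: np.ndarray = field(repr=False)
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        bits = np.asarray(self.bits, dtype=np.int8)
        if ref.shape != bits.shape or ref.ndim != 1:
            raise AlignmentError("reference and bits must be 1-D and equally long")
        if not np.isin(bits, (0, 1)).all():
            raise AlignmentError("bits must be 0 or 1")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return int(self.bits.size)


@dataclass(frozen=True)
class MatchScore:
    participant_id: str
    stimulus_id: str
    version: str
    model: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise AlignmentError(f"score must be in [0, 1], got {self.score}")


def correct_keypresses(log: KeyPressLog) -> np.ndarray:
    """Subtract the participant's baseline RT from each raw press time.

    Times that would become negative are clamped to 0.  Ordering (weak, after
    clamping) is preserved.
    """
    if log.baseline_rt is None or not log.baseline_rt > 0:
        raise ConfigError("keypress log has no positive baseline_rt")
    raw = np.asarray(log.press_times, dtype=float)
    return np.maximum(raw - log.baseline_rt, 0.0)


def assign_to_global(
    corrected_times: Sequence[float] | np.ndarray, global_array: np.ndarray
) -> LogicalArray:
    """Snap each press to its nearest reference time (ties to the earlier
    time); presses landing on one time set its bit once."""
    ref = np.asarray(global_array, dtype=float)
    if ref.size == 0:
        raise InsufficientDataError("global array is empty")
    if np.any(np.diff(ref) < 0):
        raise AlignmentError("global array must be sorted")
    times = np.asarray(corrected_times, dtype=float)
    bits = np.zeros(ref.size, dtype=np.int8)
    if times.size:
        idx = np.searchsorted(ref, times)  # first ref >= t
        idx = np.clip(idx, 0, ref.size - 1)
        left = np.clip(idx - 1, 0, ref.size - 1)
        # choose the earlier neighbour when it is at least as close
        dist_left = np.abs(times - ref[left])
        dist_right = np.abs(ref[idx] - times)
        choose_left = (idx > 0) & (dist_left <= dist_right)
        nearest = np.where(choose_left, left, idx)
        bits[nearest] = 1
    return LogicalArray(reference=ref, bits=bits)


def assignment_collisions(
    corrected_times: Sequence[float] | np.ndarray, global_array: np.ndarray
) -> int:
    """QC metric: number of presses beyond the first mapped to each time."""
    ref = np.asarray(global_array, dtype=float)
    times = np.asarray(corrected_times, dtype=float)
    if times.size == 0:
        return 0
    arr = assign_to_global(times, ref)
    return int(times.size - arr.bits.sum())


def model_logical_arrays(model_set: CueModelSet) -> dict[str, LogicalArray]:
    """One logical array per model over the set's global array (1 marks the
    model's own points, 0 the points of other models)."""
    ref = model_set.global_array
    if ref.size == 0:
        raise InsufficientDataError("global array is empty")
    out = {}
    for model in MODELS:
        times = np.array([p.time for p in model_set.points_by_model[model]])
        bits = np.isin(np.round(ref, 6), np.round(times, 6)).astype(np.int8)
        out[model] = LogicalArray(reference=ref, bits=bits)
    return out


def russell_rao(x: LogicalArray, y: LogicalArray) -> float:
    """Russell-Rao binary similarity: co-present positions over array length."""
    if len(x) != len(y) or not np.array_equal(x.reference, y.reference):
        raise AlignmentError("logical arrays do not share a reference")
    n = len(x)
    if n == 0:
        raise InsufficientDataError("empty logical arrays")
    a = int(np.sum((x.bits == 1) & (y.bits == 1)))
    return a / n


def match_participant(log: KeyPressLog, model_set: CueModelSet) -> list[MatchScore]:
    """Russell-Rao adherence of one participant's log to each of the seven
    models of the matching stimulus version."""
    if model_set.global_array.size == 0:
        raise InsufficientDataError("global array is empty")
    if log.stimulus_id != model_set.stimulus_id or log.version != model_set.version:
        raise AlignmentError(
            f"log is for {log.stimulus_id}/{log.version}, model set for "
            f"{model_set.stimulus_id}/{model_set.version}"
        )
    corrected = correct_keypresses(log)
    participant = assign_to_global(corrected, model_set.global_array)
    scores = []
    for model, arr in model_logical_arrays(model_set).items():
        scores.append(
            MatchScore(
                participant_id=log.participant_id,
                stimulus_id=log.stimulus_id,
                version=log.version,
                model=model,
                score=russell_rao(participant, arr),
            )
        )
    return scores


def scores_to_frame(scores: Iterable[MatchScore], instruction_by_participant=None) -> pd.DataFrame:
    """Long-format score table (one row per participant x stimulus x version
    x model); optionally annotates instruction group."""
    rows = [
        {
            "participant_id": s.participant_id,
            "stimulus_id": s.stimulus_id,
            "version": s.version,
            "model": s.model,
            "score": s.score,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows, columns=["participant_id", "stimulus_id", "version", "model", "score"])
    if instruction_by_participant is not None:
        df.insert(1, "instruction", df["participant_id"].map(instruction_by_participant))
    return df
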