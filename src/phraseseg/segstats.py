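"""Segment-length metrics per participant x stimulus x version.

A keypress marks a phrase *ending*, so segments are anchored at time 0: the
boundaries are ``{0} | presses`` and each press closes one segment.  The
stretch after the final press has no closing press and is not counted (an
``intervals_only`` mode that uses only between-press intervals is available).
Corrected (baseline-subtracted) press times are the intended input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["SegmentStats", "segment_lengths", "segment_table", "aggregate_segments"]


@dataclass(frozen=True)
class SegmentStats:
    participant_id: str
    stimulus_id: str
    version: str
    n_segments: int
    mean_len_ms: float  # NaN when no segments
    sd_len_ms: float  # NaN when fewer than 2 segments


def segment_lengths(
    press_times: Sequence[float] | np.ndarray,
    total_duration: float | None = None,
    *,
    participant_id: str = "",
    stimulus_id: str = "",
    version: str = "",
    intervals_only: bool = False,
) -> SegmentStats:
    """Segment-length summary for one (sorted) press sequence.

    ``n_segments`` is the number of presses (each press ends a segment);
    lengths are successive differences of ``{0} | presses``.  With
    ``intervals_only`` the first segment (0 to first press) is excluded.
    ``total_duration`` is accepted for interface symmetry but does not affect
    the metrics (no press closes the final stretch).
    """
    presses = np.asarray(sorted(press_times), dtype=float)
    if intervals_only:
        lengths = np.diff(presses)
        n = int(lengths.size)
    else:
        boundaries = np.concatenate(([0.0], presses))
        lengths = np.diff(boundaries)
        n = int(presses.size)
    mean = float(lengths.mean()) if lengths.size >= 1 else math.nan
    sd = float(lengths.std(ddof=1)) if lengths.size >= 2 else math.nan
    return SegmentStats(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        version=version,
        n_segments=n,
        mean_len_ms=mean,
        sd_len_ms=sd,
    )


def segment_table(stats: Iterable[SegmentStats], instruction_by_participant=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "stimulus_id": s.stimulus_id,
                "version": s.version,
                "n_segments": s.n_segments,
                "mean_len_ms": s.mean_len_ms,
                "sd_len_ms": s.sd_len_ms,
            }
            for s in stats
        ],
        columns=["participant_id", "stimulus_id", "version", "n_segments", "mean_len_ms", "sd_len_ms"],
    )
    if instruction_by_participant is not None:
        df.insert(1, "instruction", df["participant_id"].map(instruction_by_participant))
    return df


def aggregate_segments(
    table: pd.DataFrame,
    grouping: Sequence[str],
    *,
    values: Sequence[str] = ("n_segments", "mean_len_ms", "sd_len_ms"),
) -> pd.DataFrame:
    """Unweighted per-condition means of the segment metrics, long format.

    ``grouping`` names columns of ``table`` (e.g. ``["version",
    "instruction"]``); each value column becomes one ``metric`` level.
    """
    if table.empty:
        raise ConfigError("cannot aggregate an empty segment table")
    unknown = [g for g in grouping if g not in table.columns]
    if unknown:
        raise ConfigError(f"unknown grouping columns {unknown}")
    missing = [v for v in values if v not in table.columns]
    if missing:
        raise ConfigError(f"unknown value columns {missing}")
    grouped = table.groupby(list(grouping), sort=True)[list(values)].mean().reset_index()
    long = grouped.melt(id_vars=list(grouping), var_name="metric", value_name="mean")
    return long.sort_values(["metric", *grouping]).reset_index(drop=True)
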