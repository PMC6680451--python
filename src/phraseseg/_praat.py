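"""Minimal readers/writers for Praat long text formats (TextGrid, PitchTier).

Only the subset needed for pitch-event exchange is supported: the long
("ooTextFile") text layout, one interval tier per TextGrid, point tiers in
PitchTier. Times are seconds, as in Praat.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import ParseError

_NUM = re.compile(r"=\s*([-+0-9.eE]+)")
_TEXT = re.compile(r'=\s*"(.*)"\s*$')


def _numbers_after(lines: list[str], key: str) -> list[tuple[int, float]]:
    out = []
    for i, line in enumerate(lines):
        if line.strip().startswith(key):
            m = _NUM.search(line)
            if m:
                out.append((i, float(m.group(1))))
    return out


def read_textgrid_intervals(path: str | Path) -> tuple[list[tuple[float, float, str]], float | None]:
    """Return ``(intervals, xmax)`` from the first interval tier.

    Each interval is ``(xmin_s, xmax_s, text)``.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not any("TextGrid" in ln for ln in lines[:3]):
        raise ParseError(f"{Path(path).name}: not a TextGrid (header missing)")
    xmax_global = None
    globals_ = _numbers_after(lines, "xmax")
    if globals_:
        xmax_global = globals_[0][1]

    intervals: list[tuple[float, float, str]] = []
    i = 0
    in_tier = False
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("class") and "IntervalTier" in line:
            if in_tier:
                break  # only the first interval tier
            in_tier = True
        elif in_tier and line.startswith("intervals [") :
            xmin = xmax = None
            text = ""
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("intervals ["):
                s = lines[j].strip()
                if s.startswith("xmin"):
                    m = _NUM.search(s)
                    xmin = float(m.group(1)) if m else None
                elif s.startswith("xmax"):
                    m = _NUM.search(s)
                    xmax = float(m.group(1)) if m else None
                elif s.startswith("text"):
                    m = _TEXT.search(s)
                    text = m.group(1) if m else ""
                elif s.startswith("item [") or s.startswith("class"):
                    break
                j += 1
            if xmin is None or xmax is None:
                raise ParseError(f"{Path(path).name}: malformed interval near line {i + 1}")
            intervals.append((xmin, xmax, text))
            i = j - 1
        i += 1
    if not in_tier:
        raise ParseError(f"{Path(path).name}: no IntervalTier found")
    return intervals, xmax_global


def write_textgrid(
    intervals: list[tuple[float, float, str]],
    path: str | Path,
    *,
    xmax: float,
    tier_name: str = "events",
) -> None:
    """Write one interval tier; gaps between supplied intervals become empty
    intervals so that the tier tiles ``[0, xmax]``."""
    tiles: list[tuple[float, float, str]] = []
    cursor = 0.0
    for xmin, xmx, text in sorted(intervals):
        if xmin > cursor:
            tiles.append((cursor, xmin, ""))
        tiles.append((xmin, xmx, text))
        cursor = xmx
    if cursor < xmax:
        tiles.append((cursor, xmax, ""))
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {xmax}",
        f"        intervals: size = {len(tiles)}",
    ]
    for k, (a, b, text) in enumerate(tiles, 1):
        out += [
            f"        intervals [{k}]:",
            f"            xmin = {a}",
            f"            xmax = {b}",
            f'            text = "{text}"',
        ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_pitchtier_points(path: str | Path) -> tuple[list[tuple[float, float]], float | None]:
    """Return ``(points, xmax)``; each point is ``(time_s, value_hz)``."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not any("PitchTier" in ln for ln in lines[:3]):
        raise ParseError(f"{Path(path).name}: not a PitchTier (header missing)")
    xmax = None
    points = []
    i = 0
    while i < len(lines):
        s = lines[i].strip()
        if xmax is None and s.startswith("xmax"):
            m = _NUM.search(s)
            xmax = float(m.group(1)) if m else None
        if s.startswith("points [") or s.startswith("point ["):
            t = v = None
            j = i + 1
            while j < len(lines):
                sj = lines[j].strip()
                if sj.startswith(("number", "time")):
                    m = _NUM.search(sj)
                    t = float(m.group(1)) if m else None
                elif sj.startswith("value"):
                    m = _NUM.search(sj)
                    v = float(m.group(1)) if m else None
                    break
                elif sj.startswith(("points [", "point [")):
                    break
                j += 1
            if t is None or v is None:
                raise ParseError(f"{Path(path).name}: malformed point near line {i + 1}")
            points.append((t, v))
            i = j
        i += 1
    return points, xmax


def write_pitchtier(points: list[tuple[float, float]], path: str | Path, *, xmax: float) -> None:
    out = [
        'File type = "ooTextFile"',
        'Object class = "PitchTier"',
        "",
        "xmin = 0",
        f"xmax = {xmax}",
        f"points: size = {len(points)}",
    ]
    for k, (t, v) in enumerate(sorted(points), 1):
        out += [
            f"points [{k}]:",
            f"    number = {t}",
            f"    value = {v}",
        ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
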