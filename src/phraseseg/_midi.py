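"""Minimal Standard MIDI File reader/writer (monophonic note streams only).

Supports SMF type 0 and 1 with metrical (ticks-per-quarter) timing, note
on/off, and set-tempo meta events.  Everything else is skipped.  This is
deliberately small: the package only exchanges monophonic syllable-event
streams, never full scores.
"""

from __future__ import annotations

import struct
from pathlib import Path

from .errors import MonophonicityError, ParseError

_DEFAULT_TEMPO = 500_000  # us per quarter note (120 bpm)


def _read_varint(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise ParseError("unexpected end of track (truncated varint)")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _parse_track(data: bytes):
    """Yield (tick, kind, payload) with kind in {'on','off','tempo'}."""
    pos = 0
    tick = 0
    running = None
    while pos < len(data):
        delta, pos = _read_varint(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running = status
        else:
            if running is None:
                raise ParseError(f"running status without prior status at byte {pos}")
            status = running
        kind = status & 0xF0
        if kind in (0x80, 0x90):
            note, vel = data[pos], data[pos + 1]
            pos += 2
            if kind == 0x90 and vel > 0:
                yield tick, "on", note
            else:
                yield tick, "off", note
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:
            meta = data[pos]
            pos += 1
            length, pos = _read_varint(data, pos)
            if meta == 0x51:
                tempo = int.from_bytes(data[pos : pos + 3], "big")
                yield tick, "tempo", tempo
            pos += length
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varint(data, pos)
            pos += length
        else:
            raise ParseError(f"unsupported MIDI status byte 0x{status:02x} at {pos}")


def read_midi_notes(path: str | Path) -> list[tuple[float, float, int]]:
    """Read a monophonic SMF; return sorted ``(onset_ms, duration_ms, note)``.

    The tempo map (all set-tempo events, any track) is honoured.  A note-on
    while another note sounds raises :class:`MonophonicityError` naming the
    tick.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"MThd":
        raise ParseError(f"{Path(path).name}: not a MIDI file (no MThd)")
    hlen = struct.unpack(">I", raw[4:8])[0]
    fmt, ntracks, division = struct.unpack(">HHH", raw[8:14])
    if fmt not in (0, 1):
        raise ParseError(f"{Path(path).name}: unsupported SMF type {fmt}")
    if division & 0x8000:
        raise ParseError(f"{Path(path).name}: SMPTE timing not supported")
    pos = 8 + hlen
    messages = []  # (tick, order, kind, payload)
    for _ in range(ntracks):
        if raw[pos : pos + 4] != b"MTrk":
            raise ParseError(f"{Path(path).name}: expected MTrk at byte {pos}")
        tlen = struct.unpack(">I", raw[pos + 4 : pos + 8])[0]
        track = raw[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        try:
            messages.extend(_parse_track(track))
        except ParseError as exc:
            raise ParseError(f"{Path(path).name}: {exc}") from exc
    # note-offs before note-ons at the same tick, tempo changes first
    order = {"tempo": 0, "off": 1, "on": 2}
    messages.sort(key=lambda m: (m[0], order[m[1]]))

    # tick -> ms via tempo map
    ms_at = 0.0
    last_tick = 0
    tempo = _DEFAULT_TEMPO

    def tick_to_ms(tick: int) -> float:
        return ms_at + (tick - last_tick) * tempo / division / 1000.0

    notes = []
    active: tuple[int, float] | None = None  # (note, onset_ms)
    for tick, kind, payload in messages:
        now = tick_to_ms(tick)
        if kind == "tempo":
            ms_at, last_tick, tempo = now, tick, payload
        elif kind == "on":
            if active is not None:
                raise MonophonicityError(
                    f"{Path(path).name}: overlapping note-on at tick {tick}"
                )
            active = (payload, now)
        elif kind == "off":
            if active is not None and active[0] == payload:
                notes.append((active[1], now - active[1], active[0]))
                active = None
    notes.sort()
    return [(on, dur, note) for on, dur, note in notes if dur > 0]


def _varint(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def write_midi_notes(
    notes: list[tuple[float, float, int]],
    path: str | Path,
    *,
    tempo: int = _DEFAULT_TEMPO,
    division: int = 480,
) -> None:
    """Write sorted non-overlapping ``(onset_ms, duration_ms, note)`` as SMF type 0."""
    ms_per_tick = tempo / division / 1000.0
    events = []  # (tick, order, status, note)
    last_off = -1.0
    for onset, dur, note in sorted(notes):
        if onset < last_off - 1e-9:
            raise MonophonicityError("notes overlap; cannot write monophonic MIDI")
        last_off = onset + dur
        on_tick = round(onset / ms_per_tick)
        off_tick = max(on_tick + 1, round((onset + dur) / ms_per_tick))
        events.append((on_tick, 1, 0x90, note))
        events.append((off_tick, 0, 0x80, note))
    events.sort()
    track = bytearray(b"\x00\xff\x51\x03" + tempo.to_bytes(3, "big"))
    prev = 0
    for tick, _, status, note in events:
        track += _varint(tick - prev) + bytes([status, note, 64])
        prev = tick
    track += b"\x00\xff\x2f\x00"
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, division)
    Path(path).write_bytes(
        header + b"MTrk" + struct.pack(">I", len(track)) + bytes(track)
    )
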