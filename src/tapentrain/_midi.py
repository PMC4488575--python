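"""Minimal Standard MIDI File reader for note-on onset extraction.

Only what the tapping import path needs: header parsing (format 0/1,
ticks-per-quarter-note division), track iteration with running status,
set-tempo meta events, and note-on events.  Everything else is skipped
by length.  SMPTE divisions are rejected.
"""

from __future__ import annotations

import struct

__all__ = ["MidiFormatError", "note_on_times_ms"]

_DEFAULT_US_PER_QN = 500_000  # 120 bpm


class MidiFormatError(ValueError):
    """The file is not a parseable Standard MIDI File."""


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise MidiFormatError("variable-length quantity too long")


def _parse_track(data: bytes):
    """Yield (abs_tick, kind, payload) events from one MTrk chunk body.

    kind is "tempo" (payload: microseconds per quarter note) or
    "note_on" (payload: channel number).
    """
    pos = 0
    tick = 0
    status = None
    while pos < len(data):
        delta, pos = _read_vlq(data, pos)
        tick += delta
        if pos >= len(data):
            raise MidiFormatError("truncated event")
        byte = data[pos]
        if byte >= 0x80:
            status = byte
            pos += 1
        elif status is None:
            raise MidiFormatError("running status without prior status byte")
        if status == 0xFF:
            if pos >= len(data):
                raise MidiFormatError("truncated meta event")
            meta_type = data[pos]
            length, pos = _read_vlq(data, pos + 1)
            body = data[pos:pos + length]
            if len(body) < length:
                raise MidiFormatError("truncated meta payload")
            pos += length
            if meta_type == 0x51:
                if length != 3:
                    raise MidiFormatError("malformed set-tempo event")
                yield tick, "tempo", int.from_bytes(body, "big")
            status = None  # meta events clear running status
        elif status in (0xF0, 0xF7):
            length, pos = _read_vlq(data, pos)
            pos += length
            status = None
        else:
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            payload = data[pos:pos + n_data]
            if len(payload) < n_data:
                raise MidiFormatError("truncated channel message")
            pos += n_data
            if kind == 0x90 and payload[1] > 0:
                yield tick, "note_on", status & 0x0F


def note_on_times_ms(path, channel: int = 0) -> list:
    """Per-track note-on times (ms) on one channel, via the tempo map."""
    data = path.read_bytes() if hasattr(path, "read_bytes") else \
        open(path, "rb").read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError("missing MThd header")
    header_len, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if header_len != 6:
        raise MidiFormatError(f"unexpected MThd length {header_len}")
    if fmt not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division is not supported")
    if division == 0:
        raise MidiFormatError("zero ticks per quarter note")

    pos = 14
    tracks = []
    while pos < len(data) and len(tracks) < ntrks:
        if data[pos:pos + 4] != b"MTrk":
            raise MidiFormatError("missing MTrk chunk")
        (length,) = struct.unpack(">I", data[pos + 4:pos + 8])
        body = data[pos + 8:pos + 8 + length]
        if len(body) < length:
            raise MidiFormatError("truncated MTrk chunk")
        tracks.append(list(_parse_track(body)))
        pos += 8 + length
    if len(tracks) != ntrks:
        raise MidiFormatError("track count does not match header")

    # tempo map shared across tracks (format 1 keeps it in track 0)
    tempo_events = sorted(
        (tick, us) for track in tracks
        for tick, kind, us in track if kind == "tempo")

    def tick_to_ms(tick: int) -> float:
        us_per_qn = _DEFAULT_US_PER_QN
        last_tick = 0
        elapsed_us = 0.0
        for ev_tick, ev_us in tempo_events:
            if ev_tick >= tick:
                break
            elapsed_us += (ev_tick - last_tick) * us_per_qn / division
            last_tick, us_per_qn = ev_tick, ev_us
        elapsed_us += (tick - last_tick) * us_per_qn / division
        return elapsed_us / 1000.0

    return [[tick_to_ms(tick) for tick, kind, ch in track
             if kind == "note_on" and ch == channel]
            for track in tracks]
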