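"""Minimal Standard MIDI File (format 0/1) reader and writer.

Only what improvisation capture needs: note-on/note-off events with a
tempo-map-aware tick->seconds conversion.  Handles running status,
treats note-on with velocity 0 as note-off, and skips every other
channel/meta/sysex message with the correct lengths.  SMPTE divisions
are converted directly to seconds.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

__all__ = ["SmfNote", "SmfTrack", "read_smf_file", "write_smf_file"]

DEFAULT_TEMPO = 500_000  # microseconds per quarter note (120 BPM)

# data-byte counts for channel status nibbles 0x8..0xE
_CHANNEL_DATA_LEN = {0x8: 2, 0x9: 2, 0xA: 2, 0xB: 2, 0xC: 1, 0xD: 1, 0xE: 2}


@dataclass(frozen=True)
class SmfNote:
    """A raw note event with its time already converted to seconds."""

    time: float
    kind: str  # "on" | "off"
    note: int
    velocity: int
    channel: int = 0


@dataclass
class SmfTrack:
    notes: list[SmfNote]


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes):
    """Yield (tick, kind, payload) tuples from one MTrk chunk body."""
    pos = 0
    tick = 0
    status = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte >= 0x80:
            status = byte
            pos += 1
        elif status is None:
            raise ValueError("running status with no prior status byte")
        if status == 0xFF:  # meta
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x51 and length == 3:
                yield tick, "tempo", int.from_bytes(payload, "big")
            elif meta_type == 0x2F:
                return
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            hi = status >> 4
            ndata = _CHANNEL_DATA_LEN[hi]
            d = data[pos : pos + ndata]
            pos += ndata
            channel = status & 0x0F
            if hi == 0x9 and d[1] > 0:
                yield tick, "on", (d[0], d[1], channel)
            elif hi == 0x8 or (hi == 0x9 and d[1] == 0):
                yield tick, "off", (d[0], d[1] if hi == 0x8 else 0, channel)


class _TempoMap:
    """Piecewise-constant tempo; converts absolute ticks to seconds."""

    def __init__(self, changes: list[tuple[int, int]], ticks_per_quarter: int):
        merged: dict[int, int] = {0: DEFAULT_TEMPO}
        for tick, tempo in sorted(changes):
            merged[tick] = tempo
        self._ticks = sorted(merged)
        self._tempi = [merged[t] for t in self._ticks]
        # cumulative seconds at each change point
        self._secs = [0.0]
        for i in range(1, len(self._ticks)):
            dt = self._ticks[i] - self._ticks[i - 1]
            self._secs.append(
                self._secs[-1] + dt * self._tempi[i - 1] / 1e6 / ticks_per_quarter
            )
        self._tpq = ticks_per_quarter

    def seconds(self, tick: int) -> float:
        import bisect

        i = bisect.bisect_right(self._ticks, tick) - 1
        return (
            self._secs[i]
            + (tick - self._ticks[i]) * self._tempi[i] / 1e6 / self._tpq
        )


def read_smf_file(path) -> list[SmfTrack]:
    """Parse an SMF file into per-track note-event lists, times in seconds.

    The tempo map is built from tempo meta events in all tracks (for
    format 1 files the conductor track governs every track).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) == 0:
        return []
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File (missing MThd)")
    hlen = struct.unpack(">I", data[4:8])[0]
    fmt, ntrks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise ValueError(f"unsupported SMF format {fmt}")
    pos = 8 + hlen

    raw_tracks = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("corrupt SMF: expected MTrk chunk")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        body = data[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        raw_tracks.append(list(_parse_track(body)))

    if division & 0x8000:  # SMPTE: ticks are already wall-clock
        fps = 256 - (division >> 8)  # two's complement of high byte
        tpf = division & 0xFF
        to_seconds = lambda tick: tick / (fps * tpf)  # noqa: E731
    else:
        tempo_changes = [
            (tick, payload)
            for track in raw_tracks
            for tick, kind, payload in track
            if kind == "tempo"
        ]
        tempo_map = _TempoMap(tempo_changes, division)
        to_seconds = tempo_map.seconds

    tracks = []
    for raw in raw_tracks:
        notes = [
            SmfNote(to_seconds(tick), kind, payload[0], payload[1], payload[2])
            for tick, kind, payload in raw
            if kind in ("on", "off")
        ]
        tracks.append(SmfTrack(notes=notes))
    return tracks


def write_smf_file(
    path,
    events: list[tuple[int, str, int, int]],
    ticks_per_quarter: int = 480,
    tempo_changes: list[tuple[int, int]] | None = None,
) -> None:
    """Write a format-0 SMF. ``events`` are (tick, 'on'|'off', note, velocity);
    ``tempo_changes`` are (tick, microseconds-per-quarter)."""
    merged: list[tuple[int, int, bytes]] = []
    for tick, tempo in tempo_changes or []:
        merged.append((tick, 0, bytes([0xFF, 0x51, 0x03]) + tempo.to_bytes(3, "big")))
    for tick, kind, note, vel in events:
        status = 0x90 if kind == "on" else 0x80
        merged.append((tick, 1, bytes([status, note, vel])))
    merged.sort(key=lambda e: (e[0], e[1]))

    body = bytearray()
    prev = 0
    for tick, _, payload in merged:
        body += _write_varlen(tick - prev)
        body += payload
        prev = tick
    body += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_quarter))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
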