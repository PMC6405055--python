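"""Event-driven session tracking.

Replays a session's raw on/off stream the way a reactive state machine
would: pairs presses into note intervals (per-note FIFO), maintains the
piecewise-constant count of simultaneously held keys, and derives the
Idle/Playing state trace with running extrema of intensity, octave and
cluster size.

Intervals use the half-open convention [onset, offset): an offset that
coincides with another onset never produces a spurious count spike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import RawEvent, SessionRecord
from .keyboard import dynamics_level, note_octave

__all__ = [
    "NoteInterval",
    "HeldTimeline",
    "StateTrace",
    "pair_events",
    "playing_time",
    "held_timeline",
    "onset_sequence",
    "state_trace",
]

logger = logging.getLogger(__name__)

#: Default chord-simultaneity window, seconds (human chord spread).
CHORD_WINDOW = 0.030


@dataclass(frozen=True)
class NoteInterval:
    """A paired press: [onset, offset) in seconds, note and press velocity."""

    onset: float
    offset: float
    note: int
    velocity: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"interval must have offset > onset, got [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class HeldTimeline:
    """Piecewise-constant held-key count: counts[i] holds on
    [breakpoints[i], breakpoints[i+1])."""

    breakpoints: np.ndarray  # shape (k+1,)
    counts: np.ndarray  # shape (k,), integers >= 0

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.breakpoints) != len(self.counts) + 1:
            raise ValueError("need len(breakpoints) == len(counts) + 1")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def segment_durations(self) -> np.ndarray:
        return np.diff(self.breakpoints)

    def integral(self) -> float:
        """∫ count dt — equals the summed duration of all intervals."""
        return float(np.dot(self.counts, self.segment_durations))

    def positive_time(self) -> float:
        """∫ 1{count > 0} dt — the net playing time."""
        return float(self.segment_durations[self.counts > 0].sum())

    def positive_segments(self) -> list[tuple[float, float, int]]:
        """Maximal constant-count segments with count >= 1, merged across
        breakpoints that do not change the count."""
        segs: list[tuple[float, float, int]] = []
        for t0, t1, c in zip(self.breakpoints[:-1], self.breakpoints[1:], self.counts):
            if c == 0:
                continue
            if segs and segs[-1][1] == t0 and segs[-1][2] == c:
                segs[-1] = (segs[-1][0], float(t1), int(c))
            else:
                segs.append((float(t0), float(t1), int(c)))
        return segs


@dataclass
class StateTrace:
    """Idle/Playing trace plus cluster-size changes and running extrema."""

    states: list[tuple[float, str]]  # (time, "Idle"|"Playing") entries
    cluster_changes: list[tuple[float, int]]  # (time, held count)
    max_intensity: int | None = None
    min_intensity: int | None = None
    max_octave: int | None = None
    min_octave: int | None = None
    max_cluster: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=["time", "state"])


def pair_events(
    events: list[RawEvent], t_end: float | None = None
) -> list[NoteInterval]:
    """Pair on/off events per note, FIFO, into NoteIntervals.

    A dangling note-on is closed at ``t_end`` (warning); an unmatched
    note-off is dropped (warning).  Zero-length pairs are discarded.
    """
    open_notes: dict[int, list[RawEvent]] = {}
    intervals: list[NoteInterval] = []
    for ev in sorted(events, key=RawEvent.sort_key):
        if ev.kind == "on":
            open_notes.setdefault(ev.note, []).append(ev)
        else:
            queue = open_notes.get(ev.note)
            if not queue:
                logger.warning("unmatched note-off for note %d at t=%g dropped",
                               ev.note, ev.time)
                continue
            on = queue.pop(0)
            if ev.time > on.time:
                intervals.append(NoteInterval(on.time, ev.time, ev.note, on.velocity))
    closing = t_end if t_end is not None else max(
        (e.time for e in events), default=0.0
    )
    for note, queue in open_notes.items():
        for on in queue:
            logger.warning(
                "dangling note-on for note %d at t=%g closed at t_end=%g",
                note, on.time, closing,
            )
            if closing > on.time:
                intervals.append(NoteInterval(on.time, closing, note, on.velocity))
    intervals.sort(key=lambda iv: (iv.onset, iv.note))
    return intervals


def playing_time(intervals: list[NoteInterval]) -> float:
    """Lebesgue measure of the union of the [onset, offset) intervals."""
    if not intervals:
        return 0.0
    total = 0.0
    cur_start = cur_end = None
    for iv in sorted(intervals, key=lambda iv: iv.onset):
        if cur_end is None or iv.onset > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = iv.onset, iv.offset
        else:
            cur_end = max(cur_end, iv.offset)
    total += cur_end - cur_start
    return total


def held_timeline(
    intervals: list[NoteInterval],
    t0: float | None = None,
    t_end: float | None = None,
) -> HeldTimeline:
    """Held-key count over time; changes only at onsets and offsets.

    With no intervals, returns a single zero segment over the session
    bounds (or a unit dummy segment when no bounds are known).
    """
    lo = t0 if t0 is not None else min((iv.onset for iv in intervals), default=0.0)
    hi = t_end if t_end is not None else max(
        (iv.offset for iv in intervals), default=lo + 1.0
    )
    if hi <= lo:
        hi = lo + 1.0
    if not intervals:
        return HeldTimeline(np.array([lo, hi]), np.array([0]))

    deltas: dict[float, int] = {}
    for iv in intervals:
        deltas[iv.onset] = deltas.get(iv.onset, 0) + 1
        deltas[iv.offset] = deltas.get(iv.offset, 0) - 1
    times = sorted(set(deltas) | {lo, hi})
    times = [t for t in times if lo <= t <= hi]
    counts = []
    running = 0
    for t in times[:-1]:
        running_change = deltas.get(t, 0)
        running += running_change
        counts.append(running)
    # merge zero-length artifacts should not occur (times strictly ascending)
    return HeldTimeline(np.array(times), np.array(counts))


@dataclass(frozen=True)
class PressGroup:
    """One chord group: presses whose onsets fall within the chord window
    of the group's first onset."""

    onset: float
    notes: tuple[int, ...]
    velocities: tuple[int, ...]


def onset_sequence(
    intervals: list[NoteInterval], chord_window: float = 0.0
) -> list[PressGroup]:
    """Order presses by (onset, note) and group near-simultaneous onsets.

    An onset within ``chord_window`` seconds of its group's *first* onset
    joins that group; window 0 keeps every press separate.
    """
    if chord_window < 0:
        raise ValueError("chord_window must be >= 0")
    presses = sorted(intervals, key=lambda iv: (iv.onset, iv.note))
    groups: list[PressGroup] = []
    cur: list[NoteInterval] = []
    for p in presses:
        if cur and p.onset - cur[0].onset <= chord_window:
            cur.append(p)
        else:
            if cur:
                groups.append(_close_group(cur))
            cur = [p]
    if cur:
        groups.append(_close_group(cur))
    return groups


def _close_group(members: list[NoteInterval]) -> PressGroup:
    return PressGroup(
        onset=members[0].onset,
        notes=tuple(m.note for m in members),
        velocities=tuple(m.velocity for m in members),
    )


def state_trace(session: SessionRecord) -> StateTrace:
    """Replay a session into its Idle/Playing trace with running extrema.

    Playing holds exactly while the held-key count is >= 1.  The trace
    also records every cluster-size configuration change and the running
    max/min of intensity level, octave and cluster size.
    """
    intervals = pair_events(session.events, t_end=session.t_end)
    tl = held_timeline(intervals, t0=session.t0, t_end=session.t_end)

    states: list[tuple[float, str]] = []
    cluster_changes: list[tuple[float, int]] = []
    prev_state = None
    for t, c in zip(tl.breakpoints[:-1], tl.counts):
        state = "Playing" if c >= 1 else "Idle"
        if state != prev_state:
            states.append((float(t), state))
            prev_state = state
        if not cluster_changes or cluster_changes[-1][1] != c:
            cluster_changes.append((float(t), int(c)))
    if not states:
        states = [(session.t0, "Idle")]

    trace = StateTrace(states=states, cluster_changes=cluster_changes)
    if intervals:
        levels = [dynamics_level(iv.velocity) for iv in intervals]
        octaves = [note_octave(iv.note) for iv in intervals]
        trace.max_intensity = max(levels)
        trace.min_intensity = min(levels)
        trace.max_octave = max(octaves)
        trace.min_octave = min(octaves)
        trace.max_cluster = int(tl.counts.max())
    return trace
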