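"""Shared fixtures: session builders and the brute-force grid oracle."""

from __future__ import annotations

import numpy as np
import pytest

from improvkit.io import RawEvent, SessionRecord
from improvkit.tracker import NoteInterval

GRID_STEP = 0.001  # 1 ms


def make_session(intervals, session_id="s", t_end=None, **meta) -> SessionRecord:
    """Session from (onset, offset, note, velocity) tuples."""
    events = []
    for onset, offset, note, vel in intervals:
        events.append(RawEvent(onset, "on", note, vel))
        events.append(RawEvent(offset, "off", note))
    return SessionRecord(session_id=session_id, events=events, t_end=t_end, **meta)


def grid_counts(intervals: list[NoteInterval], t_end: float) -> np.ndarray:
    """Held-key count sampled on a 1-ms grid (midpoint of each cell)."""
    n = int(round(t_end / GRID_STEP))
    t = (np.arange(n) + 0.5) * GRID_STEP
    counts = np.zeros(n, dtype=int)
    for iv in intervals:
        counts += (t >= iv.onset) & (t < iv.offset)
    return counts


def random_intervals(rng: np.random.Generator, max_n=10, span=20.0):
    """Random interval set on a millisecond lattice (so the grid oracle is
    exact, not just within one step)."""
    n = rng.integers(1, max_n + 1)
    out = []
    for _ in range(n):
        onset = rng.integers(0, int(span * 1000) - 10) / 1000.0
        dur = rng.integers(1, 5000) / 1000.0
        offset = min(onset + dur, span)
        note = int(rng.integers(28, 104))
        out.append(NoteInterval(onset, offset, note, int(rng.integers(1, 128))))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
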