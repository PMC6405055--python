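"""Per-session behavioral parameters and cohort aggregation.

Turns one improvisation into ~30 scalar parameters (time use, key use,
intensity/octave profiles, cluster configurations, press-to-press
transitions) plus three duration-weighted histograms (octave, dynamics
level, pitch class, each as percentage of playing time).  Missing
values — e.g. transition percentages of a one-press session — are NaN.

Conventions
-----------
* intensity/octave averages are press-weighted means of per-press values;
  "most used" bins are duration-weighted modes (ties break to the lower
  bin), matching histograms expressed as percentage of playing time.
* tempo-transition ties (equal consecutive inter-onset intervals) count
  as ritardando, so accelerando + ritardando = 100.
* transitions run over the ungrouped press sequence by default; pass a
  positive ``chord_window`` to group chords first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .io import Cohort, SessionRecord
from .keyboard import (
    DEFAULT_DYNAMICS,
    DEFAULT_KEYBOARD,
    DynamicsScale,
    KeyboardSpec,
    PITCH_CLASS_NAMES,
    note_color,
    note_octave,
    pitch_class,
)
from .tracker import NoteInterval, held_timeline, onset_sequence, pair_events, playing_time

__all__ = [
    "SessionMetrics",
    "GroupAggregate",
    "compute_time_metrics",
    "compute_concurrent_metric",
    "compute_key_metrics",
    "compute_profiles",
    "compute_cluster_metrics",
    "compute_transition_metrics",
    "compute_session_metrics",
    "metrics_frame",
    "aggregate",
    "SCALAR_FIELDS",
]

NA = float("nan")


@dataclass
class SessionMetrics:
    """All per-session parameters; NaN marks a value the session cannot define."""

    session_id: str = ""
    # --- time use ---
    pct_playing_time: float = NA
    pct_idle_time: float = NA
    pct_start_time: float = NA
    start_time_s: float = NA
    pct_concurrent: float = NA
    total_session_min: float = NA
    # --- key use ---
    n_presses: float = 0.0
    pct_keys_used: float = NA
    presses_per_key: float = NA
    play_per_key_s: float = NA
    pct_black_presses: float = NA
    pct_white_presses: float = NA
    # --- intensity profile (dynamics level 1..10) ---
    intensity_avg: float = NA
    intensity_min: float = NA
    intensity_max: float = NA
    intensity_most_used: float = NA
    # --- octave profile ---
    octave_avg: float = NA
    octave_min: float = NA
    octave_max: float = NA
    octave_most_used: float = NA
    # --- cluster configurations ---
    cluster_instances: float = 0.0
    cluster_max: float = NA
    cluster_mode: float = NA
    pct_time_cluster_mode: float = NA
    # --- transitions ---
    pct_diminuendo: float = NA
    pct_crescendo: float = NA
    pct_same_intensity: float = NA
    pct_accelerando: float = NA
    pct_ritardando: float = NA
    pct_wb: float = NA
    pct_bw: float = NA
    pct_bb: float = NA
    pct_ww: float = NA
    # --- histograms (percentage of playing time) ---
    pitch_class_pct: dict = field(default_factory=dict)
    octave_hist: dict = field(default_factory=dict)
    intensity_hist: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to a scalar dict (histograms expand to prefixed columns)."""
        row = {f.name: getattr(self, f.name) for f in fields(self)
               if f.name not in ("pitch_class_pct", "octave_hist", "intensity_hist")}
        for name, pct in self.pitch_class_pct.items():
            row[f"pc_{name}"] = pct
        for octv, pct in self.octave_hist.items():
            row[f"oct_{octv}"] = pct
        for lvl, pct in self.intensity_hist.items():
            row[f"lvl_{lvl}"] = pct
        return row


SCALAR_FIELDS = [
    f.name
    for f in fields(SessionMetrics)
    if f.name not in ("session_id", "pitch_class_pct", "octave_hist", "intensity_hist")
]


@dataclass
class GroupAggregate:
    """Mean (M) and standard error (SEM) of each parameter within a group."""

    label: str
    n: int
    mean: dict
    sem: dict

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one session")


# ---------------------------------------------------------------------------
# per-session sub-computations


def _intervals(session: SessionRecord) -> list[NoteInterval]:
    return pair_events(session.events, t_end=session.t_end)


def compute_time_metrics(session: SessionRecord) -> dict:
    """Session-time breakdown: % playing, % idle, start time and % start."""
    span = session.duration
    if span <= 0:
        raise ValueError(f"session {session.session_id!r} has zero length")
    ivs = _intervals(session)
    play = playing_time(ivs)
    out = {
        "pct_playing_time": 100.0 * play / span,
        "pct_idle_time": 100.0 * (1.0 - play / span),
        "total_session_min": span / 60.0,
    }
    if ivs:
        start = min(iv.onset for iv in ivs) - session.t0
        out["start_time_s"] = start
        out["pct_start_time"] = 100.0 * start / span
    else:
        out["start_time_s"] = NA
        out["pct_start_time"] = NA
    return out


def compute_concurrent_metric(session: SessionRecord) -> float:
    """100 · (∫ held-key count dt) / net playing time; >= 100 when anything
    sounds (two keys held throughout the playing time yield 200%)."""
    ivs = _intervals(session)
    play = playing_time(ivs)
    if play <= 0:
        return NA
    tl = held_timeline(ivs, t0=session.t0, t_end=session.t_end)
    return 100.0 * tl.integral() / play


def compute_key_metrics(
    session: SessionRecord, keyboard: KeyboardSpec = DEFAULT_KEYBOARD
) -> dict:
    """Press counts, keyboard coverage and black/white press shares."""
    ivs = _intervals(session)
    n = len(ivs)
    out = {"n_presses": float(n)}
    if n == 0:
        out.update(
            pct_keys_used=NA, presses_per_key=NA, play_per_key_s=NA,
            pct_black_presses=NA, pct_white_presses=NA,
        )
        return out
    distinct = len({iv.note for iv in ivs})
    n_black = sum(1 for iv in ivs if note_color(iv.note) == "black")
    out["pct_keys_used"] = 100.0 * distinct / keyboard.n_keys
    out["presses_per_key"] = n / distinct
    out["play_per_key_s"] = sum(iv.duration for iv in ivs) / n
    out["pct_black_presses"] = 100.0 * n_black / n
    out["pct_white_presses"] = 100.0 * (n - n_black) / n
    return out


def _weighted_mode(weights: dict, tie_low: bool = True):
    """Key with the largest weight; ties break to the smaller key."""
    best = None
    for key in sorted(weights):
        if best is None or weights[key] > weights[best] + 1e-12:
            best = key
    return best


def compute_profiles(
    session: SessionRecord,
    keyboard: KeyboardSpec = DEFAULT_KEYBOARD,
    dynamics: DynamicsScale = DEFAULT_DYNAMICS,
    duration_weighted_mode: bool = True,
) -> dict:
    """Intensity/octave summary values plus the three duration-weighted
    histograms (octave, dynamics level, pitch class) as % of playing time.

    Histogram denominators are summed note-sounding seconds (one second
    of a two-note chord contributes one second to each note's bin).
    """
    ivs = _intervals(session)
    out: dict = {"pitch_class_pct": {}, "octave_hist": {}, "intensity_hist": {}}
    if not ivs:
        out.update(
            intensity_avg=NA, intensity_min=NA, intensity_max=NA,
            intensity_most_used=NA, octave_avg=NA, octave_min=NA,
            octave_max=NA, octave_most_used=NA,
        )
        return out

    levels = [dynamics.level(iv.velocity) for iv in ivs]
    octaves = [note_octave(iv.note) for iv in ivs]
    durations = [iv.duration for iv in ivs]
    total = sum(durations)

    lvl_w: dict[int, float] = {}
    oct_w: dict[int, float] = {}
    pc_w: dict[int, float] = {}
    for iv, lvl, octv, dur in zip(ivs, levels, octaves, durations):
        lvl_w[lvl] = lvl_w.get(lvl, 0.0) + dur
        oct_w[octv] = oct_w.get(octv, 0.0) + dur
        pc = pitch_class(iv.note)
        pc_w[pc] = pc_w.get(pc, 0.0) + dur

    if duration_weighted_mode:
        lvl_mode, oct_mode = _weighted_mode(lvl_w), _weighted_mode(oct_w)
    else:  # press-weighted variant
        lvl_mode = _weighted_mode({k: levels.count(k) for k in set(levels)})
        oct_mode = _weighted_mode({k: octaves.count(k) for k in set(octaves)})

    out.update(
        intensity_avg=float(np.mean(levels)),
        intensity_min=float(min(levels)),
        intensity_max=float(max(levels)),
        intensity_most_used=float(lvl_mode),
        octave_avg=float(np.mean(octaves)),
        octave_min=float(min(octaves)),
        octave_max=float(max(octaves)),
        octave_most_used=float(oct_mode),
    )
    out["pitch_class_pct"] = {
        PITCH_CLASS_NAMES[pc]: 100.0 * pc_w.get(pc, 0.0) / total for pc in range(12)
    }
    out["octave_hist"] = {
        octv: 100.0 * oct_w.get(octv, 0.0) / total for octv in keyboard.octaves()
    }
    out["intensity_hist"] = {
        lvl: 100.0 * lvl_w.get(lvl, 0.0) / total
        for lvl in range(1, dynamics.n_levels + 1)
    }
    return out


def compute_cluster_metrics(session: SessionRecord) -> dict:
    """Cluster-configuration statistics from the held-key timeline.

    An *instance* is a maximal constant-count segment with count >= 1;
    the mode is the duration-weighted modal count (ties to the smaller
    cluster)."""
    ivs = _intervals(session)
    if not ivs:
        return {
            "cluster_instances": 0.0, "cluster_max": NA,
            "cluster_mode": NA, "pct_time_cluster_mode": NA,
        }
    tl = held_timeline(ivs, t0=session.t0, t_end=session.t_end)
    segs = tl.positive_segments()
    weights: dict[int, float] = {}
    for t0, t1, c in segs:
        weights[c] = weights.get(c, 0.0) + (t1 - t0)
    mode = _weighted_mode(weights)
    play = sum(weights.values())
    return {
        "cluster_instances": float(len(segs)),
        "cluster_max": float(max(c for _, _, c in segs)),
        "cluster_mode": float(mode),
        "pct_time_cluster_mode": 100.0 * weights[mode] / play,
    }


def compute_transition_metrics(
    session: SessionRecord, chord_window: float = 0.0
) -> dict:
    """Press-to-press transition shares.

    Velocity pairs -> crescendo/diminuendo/same; key-color pairs ->
    ww/wb/bw/bb; consecutive inter-onset-interval pairs -> accelerando
    (shortening) / ritardando (lengthening or equal).  Each family is a
    percentage of its own pair count and sums to 100 when defined.
    """
    groups = onset_sequence(_intervals(session), chord_window=chord_window)
    out = {
        "pct_diminuendo": NA, "pct_crescendo": NA, "pct_same_intensity": NA,
        "pct_accelerando": NA, "pct_ritardando": NA,
        "pct_wb": NA, "pct_bw": NA, "pct_bb": NA, "pct_ww": NA,
    }
    # per-group representative velocity/color: the press itself when
    # ungrouped; loudest member / first note for chords
    vels = [max(g.velocities) for g in groups]
    colors = [note_color(g.notes[0]) for g in groups]
    onsets = [g.onset for g in groups]

    if len(groups) >= 2:
        n_pairs = len(groups) - 1
        up = sum(1 for a, b in zip(vels, vels[1:]) if b > a)
        dn = sum(1 for a, b in zip(vels, vels[1:]) if b < a)
        out["pct_crescendo"] = 100.0 * up / n_pairs
        out["pct_diminuendo"] = 100.0 * dn / n_pairs
        out["pct_same_intensity"] = 100.0 * (n_pairs - up - dn) / n_pairs
        combos = {"ww": 0, "wb": 0, "bw": 0, "bb": 0}
        for a, b in zip(colors, colors[1:]):
            combos[a[0] + b[0]] += 1
        for k, v in combos.items():
            out[f"pct_{k}"] = 100.0 * v / n_pairs
    if len(groups) >= 3:
        iois = np.diff(onsets)
        n_pairs = len(iois) - 1
        accel = int(np.sum(iois[1:] < iois[:-1]))
        out["pct_accelerando"] = 100.0 * accel / n_pairs
        out["pct_ritardando"] = 100.0 * (n_pairs - accel) / n_pairs
    return out


def compute_session_metrics(
    session: SessionRecord,
    keyboard: KeyboardSpec = DEFAULT_KEYBOARD,
    dynamics: DynamicsScale = DEFAULT_DYNAMICS,
    chord_window: float = 0.0,
) -> SessionMetrics:
    """All parameters for one session; sub-results that the session cannot
    define (e.g. transitions of a single press) stay NaN."""
    m = SessionMetrics(session_id=session.session_id)
    vals: dict = {}
    vals.update(compute_time_metrics(session))
    vals["pct_concurrent"] = compute_concurrent_metric(session)
    vals.update(compute_key_metrics(session, keyboard))
    vals.update(compute_profiles(session, keyboard, dynamics))
    vals.update(compute_cluster_metrics(session))
    vals.update(compute_transition_metrics(session, chord_window=chord_window))
    for k, v in vals.items():
        setattr(m, k, v)
    return m


# ---------------------------------------------------------------------------
# cohort aggregation


def metrics_frame(
    cohort: Cohort | list[SessionRecord],
    keyboard: KeyboardSpec = DEFAULT_KEYBOARD,
    **kwargs,
) -> pd.DataFrame:
    """One row per session: metadata + flattened SessionMetrics columns."""
    rows = []
    for s in cohort:
        row = compute_session_metrics(s, keyboard=keyboard, **kwargs).to_row()
        row.update(
            participant_id=s.participant_id, task=s.task, gender=s.gender,
            age=s.age, proficiency=s.proficiency,
        )
        rows.append(row)
    return pd.DataFrame(rows)


DURATION_LABELS = ("extremely short", "short", "medium", "long", "extremely long")


def session_length_labels(frame: pd.DataFrame) -> pd.Series:
    """Descriptive quintile labels of session length over a cohort.

    Reported alongside metrics for documentation; never used in
    statistics (absolute duration cut-offs are not meaningful across
    settings, so cohort-relative quintiles are used instead).
    """
    minutes = pd.to_numeric(frame["total_session_min"])
    return pd.qcut(minutes, 5, labels=DURATION_LABELS)


VALENCE_MAP = {
    "ugly": "negative-valence",
    "negative": "negative-valence",
    "beautiful": "positive-valence",
    "positive": "positive-valence",
}


def group_labels(frame: pd.DataFrame, grouping) -> pd.Series:
    """Resolve a grouping spec into per-session labels.

    ``grouping`` is one of 'task', 'gender', 'proficiency', 'age'
    (median split, over-median -> 'old'), 'valence' (collapses
    ugly/negative and beautiful/positive), a column name, or a callable
    row -> label.
    """
    if callable(grouping):
        return frame.apply(grouping, axis=1)
    if grouping == "age":
        ages = pd.to_numeric(frame["age"])
        median = ages.median()
        return pd.Series(
            np.where(ages > median, "old", "young"), index=frame.index
        )
    if grouping == "valence":
        return frame["task"].map(lambda t: VALENCE_MAP.get(t, t))
    if grouping in frame.columns:
        return frame[grouping].astype(str)
    raise ValueError(f"unknown grouping {grouping!r}")


def aggregate(
    frame: pd.DataFrame, grouping="task", parameters: list[str] | None = None
) -> list[GroupAggregate]:
    """Per-group mean and SEM (sd/√n) of each parameter, NaN excluded
    pairwise per parameter."""
    params = parameters or [c for c in SCALAR_FIELDS if c in frame.columns]
    labels = group_labels(frame, grouping)
    out = []
    for label, idx in sorted(labels.groupby(labels).groups.items()):
        sub = frame.loc[idx, params]
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        means, sems = {}, {}
        for p in params:
            col = pd.to_numeric(sub[p], errors="coerce").dropna()
            means[p] = float(col.mean()) if len(col) else NA
            sems[p] = (
                float(col.std(ddof=1) / math.sqrt(len(col))) if len(col) > 1
                else (0.0 if len(col) == 1 else NA)
            )
        out.append(GroupAggregate(label=str(label), n=len(sub), mean=means, sem=sems))
    return out
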