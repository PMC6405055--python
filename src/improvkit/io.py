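"""Readers and writers for improvisation event data.

Three sources normalise onto the same in-memory containers: Standard
MIDI Files, a canonical tab-separated event table, and the de-identified
participant deposit (a loosely specified text file read by a tolerant,
dialect-sniffing parser).  All times are seconds from session start.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from . import smf as _smf

__all__ = [
    "RawEvent",
    "SessionRecord",
    "Cohort",
    "TABLE_COLUMNS",
    "read_smf",
    "read_event_table",
    "write_event_table",
    "read_s1_dataset",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = (
    "session_id",
    "participant_id",
    "task",
    "gender",
    "age",
    "proficiency",
    "time_s",
    "kind",
    "note",
    "velocity",
)

_KIND_ORDER = {"off": 0, "on": 1}  # off before on at equal times


@dataclass(frozen=True, order=False)
class RawEvent:
    """One key press or release: seconds from session start, note, velocity."""

    time: float
    kind: str  # "on" | "off"
    note: int
    velocity: int = 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.kind not in ("on", "off"):
            raise ValueError(f"event kind must be 'on' or 'off', got {self.kind!r}")
        if not 0 <= int(self.note) <= 127:
            raise ValueError(f"note out of range 0..127: {self.note}")
        if not 0 <= int(self.velocity) <= 127:
            raise ValueError(f"velocity out of range 0..127: {self.velocity}")

    def sort_key(self):
        return (self.time, _KIND_ORDER[self.kind], self.note)


@dataclass
class SessionRecord:
    """One improvisation: metadata, ordered events and session bounds."""

    session_id: str
    participant_id: str = ""
    task: str = ""
    gender: str = ""
    age: float | None = None
    proficiency: str = ""
    events: list[RawEvent] = field(default_factory=list)
    t0: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=RawEvent.sort_key)
        if self.t_end is None:
            self.t_end = max((e.time for e in self.events), default=self.t0)
        if self.t_end < self.t0:
            raise ValueError("t_end must be >= t0")
        for e in self.events:
            if not self.t0 <= e.time <= self.t_end:
                raise ValueError(
                    f"event at t={e.time} outside session bounds "
                    f"[{self.t0}, {self.t_end}]"
                )

    @property
    def duration(self) -> float:
        return self.t_end - self.t0


@dataclass
class Cohort:
    """A set of improvisation sessions with unique ids."""

    sessions: list[SessionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate session_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def task_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sessions:
            counts[s.task] = counts.get(s.task, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Standard MIDI Files


def read_smf(path, merge_tracks: bool = False, session_id: str | None = None) -> list[SessionRecord]:
    """Read an SMF into SessionRecords, one per track holding notes.

    Tick times are converted to seconds through the file's tempo map;
    note-on with velocity 0 is treated as note-off.  With
    ``merge_tracks=True`` all tracks collapse into a single session.
    """
    tracks = _smf.read_smf_file(path)
    base = session_id or str(path)
    note_tracks = [t for t in tracks if t.notes]
    if merge_tracks and note_tracks:
        notes = sorted(
            (n for t in note_tracks for n in t.notes), key=lambda n: n.time
        )
        note_tracks = [_smf.SmfTrack(notes=notes)]
    sessions = []
    for i, track in enumerate(note_tracks):
        events = [
            RawEvent(n.time, n.kind, n.note, n.velocity) for n in track.notes
        ]
        sid = base if len(note_tracks) == 1 else f"{base}#{i}"
        sessions.append(SessionRecord(session_id=sid, events=events))
    return sessions


# ---------------------------------------------------------------------------
# Canonical event table (TSV)


def read_event_table(path) -> list[SessionRecord]:
    """Read the canonical TSV of note events grouped by session_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing required columns: {missing}")
    sessions = []
    for sid, grp in df.groupby("session_id", sort=True):
        events = []
        for idx, row in grp.iterrows():
            try:
                events.append(
                    RawEvent(
                        time=float(row["time_s"]),
                        kind=str(row["kind"]),
                        note=int(row["note"]),
                        velocity=int(row["velocity"]) if row["velocity"] != "" else 0,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"bad event row at line {idx + 2}: {exc}") from exc
        first = grp.iloc[0]
        sessions.append(
            SessionRecord(
                session_id=str(sid),
                participant_id=str(first["participant_id"]),
                task=str(first["task"]),
                gender=str(first["gender"]),
                age=float(first["age"]) if first["age"] != "" else None,
                proficiency=str(first["proficiency"]),
                events=events,
            )
        )
    return sessions


def write_event_table(cohort: Cohort | list[SessionRecord], path) -> None:
    """Write the canonical TSV; deterministic order (session_id, time, note)."""
    sessions = list(cohort)
    rows = []
    for s in sorted(sessions, key=lambda s: s.session_id):
        for e in sorted(s.events, key=RawEvent.sort_key):
            rows.append(
                {
                    "session_id": s.session_id,
                    "participant_id": s.participant_id,
                    "task": s.task,
                    "gender": s.gender,
                    "age": "" if s.age is None else f"{s.age:g}",
                    "proficiency": s.proficiency,
                    "time_s": f"{e.time:.6f}",
                    "kind": e.kind,
                    "note": e.note,
                    "velocity": e.velocity,
                }
            )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# De-identified participant deposit (tolerant reader)

_COLUMN_ALIASES = {
    "session_id": ("session_id", "session", "improvisation", "improv_id", "sample"),
    "participant_id": ("participant_id", "participant", "subject", "subj", "id"),
    "task": ("task", "title", "condition", "improvisation_task", "notion"),
    "gender": ("gender", "sex"),
    "age": ("age", "age_years"),
    "proficiency": ("proficiency", "musicianship", "training", "level"),
    "time_s": ("time_s", "time", "timestamp", "t", "onset_time", "time_sec"),
    "kind": ("kind", "type", "event", "event_type", "onoff", "status"),
    "note": ("note", "note_number", "pitch", "key", "midi_note"),
    "velocity": ("velocity", "vel", "intensity", "pressure"),
}


def _sniff_delimiter(lines: list[str]) -> str:
    counts = {d: sum(line.count(d) for line in lines) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else r"\s+"


def _match_columns(header: list[str]) -> dict[str, str]:
    mapping = {}
    lowered = {re.sub(r"[^a-z0-9_]", "", h.lower().replace(" ", "_")): h for h in header}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canonical] = lowered[alias]
                break
    return mapping


def read_s1_dataset(path) -> Cohort:
    """Read the deposited de-identified dataset with dialect auto-detection.

    The deposit's exact layout is not formally specified, so the reader
    sniffs the delimiter, fuzzily matches column names onto the canonical
    schema, logs the inferred dialect, and raises an explicit
    "unrecognized dialect" error (listing what it did detect) when the
    required columns cannot be located.  Event-level layouts produce
    sessions with events; summary layouts (one row per improvisation,
    no event columns) produce metadata-only sessions whose parameter
    columns are preserved on the returned frame for downstream use.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        raw_lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not raw_lines:
        return Cohort(sessions=[])
    sep = _sniff_delimiter(raw_lines[:50])
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, comment="#",
                     skip_blank_lines=True, keep_default_na=False)
    mapping = _match_columns(list(df.columns))
    logger.info(
        "deposit dialect: delimiter=%r, matched columns %s", sep, mapping
    )

    has_events = all(k in mapping for k in ("time_s", "kind", "note"))
    has_session = "session_id" in mapping or (
        "participant_id" in mapping and "task" in mapping
    )
    if not has_session:
        raise ValueError(
            "unrecognized dialect: could not locate session identifiers; "
            f"detected delimiter {sep!r} and columns {list(df.columns)}"
        )

    def col(name, default=""):
        return df[mapping[name]] if name in mapping else default

    if "session_id" in mapping:
        sids = df[mapping["session_id"]]
    else:
        sids = col("participant_id") + ":" + col("task")

    work = pd.DataFrame(
        {
            "session_id": sids,
            "participant_id": col("participant_id"),
            "task": col("task"),
            "gender": col("gender"),
            "age": col("age"),
            "proficiency": col("proficiency"),
        }
    )
    sessions = []
    if has_events:
        work["time_s"] = df[mapping["time_s"]]
        work["kind"] = df[mapping["kind"]].str.lower().str.strip()
        work["kind"] = work["kind"].replace(
            {"noteon": "on", "note_on": "on", "1": "on",
             "noteoff": "off", "note_off": "off", "0": "off"}
        )
        work["note"] = df[mapping["note"]]
        work["velocity"] = col("velocity", "0")
        for sid, grp in work.groupby("session_id", sort=True):
            first = grp.iloc[0]
            events = [
                RawEvent(
                    time=float(r["time_s"]),
                    kind=r["kind"],
                    note=int(float(r["note"])),
                    velocity=int(float(r["velocity"])) if r["velocity"] != "" else 0,
                )
                for _, r in grp.iterrows()
            ]
            sessions.append(
                SessionRecord(
                    session_id=str(sid),
                    participant_id=str(first["participant_id"]),
                    task=_canonical_task(first["task"]),
                    gender=str(first["gender"]).lower(),
                    age=float(first["age"]) if first["age"] != "" else None,
                    proficiency=str(first["proficiency"]).lower(),
                    events=events,
                )
            )
    else:
        for _, r in work.drop_duplicates("session_id").iterrows():
            sessions.append(
                SessionRecord(
                    session_id=str(r["session_id"]),
                    participant_id=str(r["participant_id"]),
                    task=_canonical_task(r["task"]),
                    gender=str(r["gender"]).lower(),
                    age=float(r["age"]) if r["age"] != "" else None,
                    proficiency=str(r["proficiency"]).lower(),
                )
            )
    return Cohort(sessions=sessions)


def _canonical_task(label: str) -> str:
    t = str(label).strip().lower()
    for canon in ("ugly", "beautiful", "negative", "positive"):
        if canon in t:
            return canon
    return t


def with_bounds(session: SessionRecord, t0: float | None = None,
                t_end: float | None = None) -> SessionRecord:
    """Return a copy of ``session`` with overridden bounds (logged)."""
    new = replace(
        session,
        t0=session.t0 if t0 is None else t0,
        t_end=session.t_end if t_end is None else t_end,
    )
    logger.info(
        "session %s bounds set to [%g, %g]", new.session_id, new.t0, new.t_end
    )
    return new
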