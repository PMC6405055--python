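"""Synthetic improvisation sessions with controllable statistical structure.

Generates keyboard sessions whose octave placement, velocity, inter-onset
timing, cluster sizes, key-color preference and idle gaps follow
configurable truncated-normal / categorical distributions, so that every
downstream metric has a known expected tendency.  Two presets encode the
qualitative contrast between harsh, low, loud, cluster-heavy playing and
gentle, mid-register, sparse playing.

All sampling is reproducible from (profile, seed); cohort generation
derives per-session seeds deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Cohort, RawEvent, SessionRecord
from .keyboard import BLACK_PITCH_CLASSES, DEFAULT_KEYBOARD, KeyboardSpec

__all__ = [
    "Dist",
    "ImprovProfile",
    "sample_session",
    "sample_cohort",
    "UGLY_LIKE",
    "BEAUTIFUL_LIKE",
]

_WHITE_CLASSES = tuple(sorted(set(range(12)) - BLACK_PITCH_CLASSES))
_BLACK_CLASSES = tuple(sorted(BLACK_PITCH_CLASSES))


@dataclass(frozen=True)
class Dist:
    """Truncated normal: mean, sd, lower bound (and optional upper bound)."""

    mean: float
    sd: float
    minimum: float = 0.0
    maximum: float | None = None

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        x = rng.normal(self.mean, self.sd, size=size)
        hi = np.inf if self.maximum is None else self.maximum
        return np.clip(x, self.minimum, hi)


@dataclass(frozen=True)
class ImprovProfile:
    """Generative description of one playing style."""

    session_duration: Dist = field(default_factory=lambda: Dist(52.0, 20.0, 10.0))
    start_delay: Dist = field(default_factory=lambda: Dist(9.0, 6.0, 0.0))
    ioi: Dist = field(default_factory=lambda: Dist(0.5, 0.3, 0.05))
    note_duration: Dist = field(default_factory=lambda: Dist(0.4, 0.25, 0.05))
    octave_center: float = 3.5
    octave_spread: float = 1.0
    velocity_center: float = 76.0
    velocity_spread: float = 18.0
    p_black: float = 0.16
    cluster_sizes: tuple[int, ...] = (1, 2, 3)
    cluster_probs: tuple[float, ...] = (0.6, 0.25, 0.15)
    idle_gap_rate: float = 0.06  # probability an onset is preceded by a gap
    idle_gap_length: Dist = field(default_factory=lambda: Dist(3.0, 2.0, 0.5))
    hold_to_next: bool = False  # legato: sustain every chord to the next onset

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_black <= 1.0:
            raise ValueError("p_black must be a probability")
        if not 0.0 <= self.idle_gap_rate <= 1.0:
            raise ValueError("idle_gap_rate must be a probability")
        if len(self.cluster_sizes) != len(self.cluster_probs):
            raise ValueError("cluster_sizes and cluster_probs must align")
        if abs(sum(self.cluster_probs) - 1.0) > 1e-9:
            raise ValueError("cluster_probs must sum to 1")
        if self.session_duration.minimum <= self.start_delay.minimum:
            pass  # start delay is clipped to the session below
        if self.session_duration.mean <= 0:
            raise ValueError("session duration must be positive")


def _pick_note(rng: np.random.Generator, profile: ImprovProfile,
               keyboard: KeyboardSpec) -> int:
    octave = int(round(np.clip(
        rng.normal(profile.octave_center, profile.octave_spread),
        keyboard.octaves().start, keyboard.octaves().stop - 1,
    )))
    classes = _BLACK_CLASSES if rng.random() < profile.p_black else _WHITE_CLASSES
    pc = int(rng.choice(classes))
    note = 12 * (octave + 1) + pc
    # clamp onto the keyboard preserving key color (shift whole octaves)
    while note < keyboard.lowest_note:
        note += 12
    while note > keyboard.highest_note:
        note -= 12
    return note


def _chord_notes(base: int, size: int, keyboard: KeyboardSpec) -> list[int]:
    """A compact physical cluster: ``size`` nearest keys of the base
    note's color, stacked upward from ``base`` (shifted down to fit the
    keyboard).  Same-color stacking keeps the configured black-key
    probability exact for every press."""
    from .keyboard import note_color

    color = note_color(base)
    same_color = [n for n in keyboard.notes if note_color(n) == color]
    idx = same_color.index(base) if base in same_color else 0
    idx = max(0, min(idx, len(same_color) - size))
    return same_color[idx : idx + size]


def sample_session(
    profile: ImprovProfile,
    keyboard: KeyboardSpec = DEFAULT_KEYBOARD,
    seed: int | np.random.SeedSequence = 0,
    session_id: str = "synthetic",
    **metadata,
) -> SessionRecord:
    """Draw one session: chords of ``cluster_size`` near-simultaneous
    onsets (within 10 ms) at neighbouring notes, truncated-normal IOIs,
    velocities and note durations, and occasional idle gaps."""
    rng = np.random.default_rng(seed)
    sd = profile.session_duration
    if sd.maximum is not None and sd.minimum > sd.maximum:
        raise ValueError("infeasible profile: session duration bounds conflict")
    duration = float(sd.sample(rng))
    if (profile.note_duration.minimum >= duration
            or profile.start_delay.minimum >= duration):
        raise ValueError(
            "infeasible profile: minimum note duration or start delay "
            "exceeds the session duration"
        )
    t = float(profile.start_delay.sample(rng))
    t = min(t, 0.9 * duration)

    events: list[RawEvent] = []
    pending: list[int] = []  # legato notes awaiting the next chord onset
    while t < duration:
        if rng.random() < profile.idle_gap_rate:
            t += float(profile.idle_gap_length.sample(rng))
            if t >= duration:
                break
        size = int(rng.choice(profile.cluster_sizes, p=np.asarray(profile.cluster_probs)))
        notes = _chord_notes(_pick_note(rng, profile, keyboard), size, keyboard)
        vel = int(round(np.clip(
            rng.normal(profile.velocity_center, profile.velocity_spread), 1, 127
        )))
        for n in pending:
            events.append(RawEvent(t, "off", n))
        pending = []
        for j, n in enumerate(notes):
            on_t = t if size == 1 else t + 0.01 * j / (size - 1)
            if on_t >= duration:
                continue
            v = int(np.clip(vel + rng.integers(-5, 6), 1, 127))
            events.append(RawEvent(on_t, "on", n, v))
            if profile.hold_to_next:
                pending.append(n)
            else:
                dur = float(profile.note_duration.sample(rng))
                events.append(RawEvent(min(on_t + dur, duration), "off", n))
        t += float(profile.ioi.sample(rng))

    for n in pending:
        events.append(RawEvent(duration, "off", n))
    return SessionRecord(
        session_id=session_id, events=events, t0=0.0, t_end=duration, **metadata
    )


def sample_cohort(
    n_per_group: int,
    profiles,
    keyboard: KeyboardSpec = DEFAULT_KEYBOARD,
    seed: int = 0,
    demographics: bool = True,
) -> Cohort:
    """A labeled cohort: ``n_per_group`` sessions per profile, per-session
    seeds spawned deterministically from the master seed.

    ``profiles`` maps group label -> ImprovProfile (a dict or an iterable
    of (label, profile) pairs; duplicate labels are rejected).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    pairs = list(profiles.items()) if isinstance(profiles, dict) else list(profiles)
    labels = [lab for lab, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    profiles = dict(pairs)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(labels) * n_per_group)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    sessions = []
    i = 0
    for label, profile in profiles.items():
        for j in range(n_per_group):
            meta = {}
            if demographics:
                meta = {
                    "gender": str(meta_rng.choice(["female", "male"])),
                    "age": float(np.clip(meta_rng.normal(33, 13), 18, 77)),
                    "proficiency": str(meta_rng.choice(["layman", "professional"])),
                }
            sessions.append(
                sample_session(
                    profile, keyboard, seed=children[i],
                    session_id=f"{label}-{j:03d}",
                    participant_id=f"p{j:03d}", task=label, **meta,
                )
            )
            i += 1
    return Cohort(sessions=sessions)


#: Harsh preset: low register, loud, cluster-heavy, black-key-leaning,
#: long think-time before the first press.
UGLY_LIKE = ImprovProfile(
    octave_center=2.5,
    velocity_center=95.0,
    p_black=0.3,
    cluster_sizes=(1, 2, 3, 4, 5, 6),
    cluster_probs=(0.15, 0.15, 0.2, 0.2, 0.15, 0.15),
    start_delay=Dist(15.0, 8.0, 0.0),
    note_duration=Dist(0.6, 0.3, 0.05),
)

#: Gentle preset: mid-high register, soft, sparse, white-key-leaning.
BEAUTIFUL_LIKE = ImprovProfile(
    octave_center=4.3,
    velocity_center=62.0,
    p_black=0.12,
    cluster_sizes=(1, 2, 3),
    cluster_probs=(0.55, 0.3, 0.15),
    start_delay=Dist(8.0, 5.0, 0.0),
    note_duration=Dist(0.45, 0.2, 0.05),
)


def preset(name: str) -> ImprovProfile:
    presets = {"ugly-like": UGLY_LIKE, "beautiful-like": BEAUTIFUL_LIKE,
               "default": ImprovProfile()}
    try:
        return presets[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")


def vary(profile: ImprovProfile, **overrides) -> ImprovProfile:
    """Copy a profile with field overrides (convenience for sweeps)."""
    return replace(profile, **overrides)
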