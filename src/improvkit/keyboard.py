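"""Note-number semantics of the piano keyboard.

Maps MIDI note numbers to key color (black/white), octave number
(scientific convention, middle C = C4 = MIDI 60) and pitch class, and
MIDI velocities to a ten-level musical dynamics scale (pppp .. ffff).

The default instrument is a 76-key controller spanning E1 (MIDI 28) to
G7 (MIDI 103): 31 black keys and 45 white keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "KeyboardSpec",
    "DynamicsScale",
    "DEFAULT_KEYBOARD",
    "DEFAULT_DYNAMICS",
    "PITCH_CLASS_NAMES",
    "BLACK_PITCH_CLASSES",
    "note_color",
    "note_octave",
    "pitch_class",
    "pitch_class_name",
    "note_name",
    "dynamics_level",
]

#: Sharp-spelled pitch-class names, index = note mod 12.
PITCH_CLASS_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")

#: Pitch classes realised as black keys on a piano (the five sharps).
BLACK_PITCH_CLASSES = frozenset({1, 3, 6, 8, 10})

#: Ten-level dynamics ladder, softest to loudest.
DYNAMICS_NAMES = ("pppp", "ppp", "pp", "p", "mp", "mf", "f", "ff", "fff", "ffff")


def _check_note(note: int) -> int:
    note = int(note)
    if not 0 <= note <= 127:
        raise ValueError(f"MIDI note number out of range 0..127: {note}")
    return note


@dataclass(frozen=True)
class KeyboardSpec:
    """Physical keyboard span in MIDI note numbers (inclusive)."""

    lowest_note: int = 28
    highest_note: int = 103

    def __post_init__(self) -> None:
        _check_note(self.lowest_note)
        _check_note(self.highest_note)
        if self.highest_note < self.lowest_note:
            raise ValueError("highest_note must be >= lowest_note")

    @property
    def n_keys(self) -> int:
        return self.highest_note - self.lowest_note + 1

    @property
    def notes(self) -> range:
        return range(self.lowest_note, self.highest_note + 1)

    def contains(self, note: int) -> bool:
        return self.lowest_note <= note <= self.highest_note

    def count_colors(self) -> tuple[int, int]:
        """Return (n_black, n_white) over the keyboard span."""
        n_black = sum(1 for n in self.notes if note_color(n) == "black")
        return n_black, self.n_keys - n_black

    def octaves(self) -> range:
        """Octave numbers reachable on this keyboard (inclusive range)."""
        lo = note_octave(self.lowest_note)
        hi = note_octave(self.highest_note)
        return range(lo, hi + 1)


@dataclass(frozen=True)
class DynamicsScale:
    """Monotone categorisation of MIDI velocity 0..127 onto levels 1..10.

    ``boundaries`` holds the lowest velocity of each level above the first,
    so level(v) = 1 + number of boundaries <= v.  The default is an
    equal-width binning, level = 1 + floor(v * 10 / 128); alternative
    published mappings can be supplied as custom boundaries.
    """

    boundaries: tuple[int, ...] = field(
        default_factory=lambda: tuple(-(-128 * k // 10) for k in range(1, 10))
    )
    level_names: tuple[str, ...] = DYNAMICS_NAMES

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.level_names) - 1:
            raise ValueError("need exactly n_levels - 1 boundaries")
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError("boundaries must be non-decreasing")

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    def level(self, velocity: int) -> int:
        velocity = int(velocity)
        if not 0 <= velocity <= 127:
            raise ValueError(f"MIDI velocity out of range 0..127: {velocity}")
        lvl = 1
        for b in self.boundaries:
            if velocity >= b:
                lvl += 1
        return lvl

    def name(self, level: int) -> str:
        return self.level_names[level - 1]


DEFAULT_KEYBOARD = KeyboardSpec()
DEFAULT_DYNAMICS = DynamicsScale()


def note_color(note: int) -> str:
    """'black' for the five sharp pitch classes, 'white' otherwise."""
    return "black" if _check_note(note) % 12 in BLACK_PITCH_CLASSES else "white"


def note_octave(note: int) -> int:
    """Scientific octave number: floor(note/12) - 1, so MIDI 60 -> 4."""
    return _check_note(note) // 12 - 1


def pitch_class(note: int) -> int:
    """Pitch class 0..11 (C=0 .. B=11)."""
    return _check_note(note) % 12


def pitch_class_name(note: int) -> str:
    return PITCH_CLASS_NAMES[pitch_class(note)]


def note_name(note: int) -> str:
    """Sharp-spelled note name with scientific octave, e.g. 60 -> 'C4'."""
    return f"{pitch_class_name(note)}{note_octave(note)}"


def dynamics_level(velocity: int, scale: DynamicsScale = DEFAULT_DYNAMICS) -> int:
    """Dynamics level 1 (pppp) .. 10 (ffff) for a MIDI velocity."""
    return scale.level(velocity)
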