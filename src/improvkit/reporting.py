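"""Textual and tabular documentation of sessions and cohorts.

Deterministic, headless renderers: a comprehensive per-session text
report, a piano-roll table (optionally a figure), and a cohort parameter
matrix of "mean (SEM)" cells with significance stars.  Every renderer is
a pure function of its inputs, and every table has a machine-readable
twin so no value is lost at rendered precision.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import SessionRecord
from .keyboard import note_color, note_name
from .metrics import GroupAggregate, SCALAR_FIELDS, SessionMetrics
from .stats import significance_stars
from .tracker import pair_events

__all__ = [
    "render_session_report",
    "piano_roll_table",
    "plot_piano_roll",
    "render_cohort_table",
    "cohort_table_frame",
]

_SECTIONS: list[tuple[str, list[tuple[str, str, str]]]] = [
    ("Time use", [
        ("pct_playing_time", "Playing time (% of session)", "pct"),
        ("pct_idle_time", "Idle time (% of session)", "pct"),
        ("start_time_s", "Start time (s)", "sec"),
        ("pct_start_time", "Start time (% of session)", "pct"),
        ("pct_concurrent", "Concurrent playing (% of playing time)", "pct"),
        ("total_session_min", "Total session (min)", "min"),
    ]),
    ("Notes and keys", [
        ("n_presses", "Number of presses", "int"),
        ("pct_keys_used", "Keys used (% of keyboard)", "pct"),
        ("presses_per_key", "Presses per key", "ratio"),
        ("play_per_key_s", "Play per press (s)", "sec"),
        ("pct_black_presses", "Black-key presses (%)", "pct"),
        ("pct_white_presses", "White-key presses (%)", "pct"),
    ]),
    ("Intensity (dynamics level 1-10)", [
        ("intensity_avg", "Average level", "ratio"),
        ("intensity_min", "Lowest level", "int"),
        ("intensity_max", "Highest level", "int"),
        ("intensity_most_used", "Most used level", "int"),
    ]),
    ("Octaves", [
        ("octave_avg", "Average octave", "ratio"),
        ("octave_min", "Lowest octave", "int"),
        ("octave_max", "Highest octave", "int"),
        ("octave_most_used", "Most used octave", "int"),
    ]),
    ("Clusters", [
        ("cluster_instances", "Cluster instances", "int"),
        ("cluster_max", "Max keys pressed together", "int"),
        ("cluster_mode", "Most pressed configuration", "int"),
        ("pct_time_cluster_mode", "Time at modal configuration (% of playing)", "pct"),
    ]),
    ("Transitions", [
        ("pct_crescendo", "Crescendo (%)", "pct"),
        ("pct_diminuendo", "Diminuendo (%)", "pct"),
        ("pct_same_intensity", "Same intensity (%)", "pct"),
        ("pct_accelerando", "Accelerando (%)", "pct"),
        ("pct_ritardando", "Ritardando (%)", "pct"),
        ("pct_ww", "White to white (%)", "pct"),
        ("pct_wb", "White to black (%)", "pct"),
        ("pct_bw", "Black to white (%)", "pct"),
        ("pct_bb", "Black to black (%)", "pct"),
    ]),
]


def _fmt(value, kind: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    if kind == "int":
        return f"{value:.0f}"
    if kind in ("pct", "sec"):
        return f"{value:.1f}"
    return f"{value:.2f}"  # ratios / averages


def render_session_report(metrics: SessionMetrics) -> str:
    """Comprehensive textual report of one improvisation's parameters.

    Fixed layout and precision (percentages and seconds to 1 decimal,
    levels as integers); missing values render as "n/a"; byte-identical
    for identical inputs.
    """
    lines = [f"Improvisation report: {metrics.session_id}", "=" * 46]
    for title, rows in _SECTIONS:
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        for field_name, label, kind in rows:
            lines.append(f"  {label:<44s} {_fmt(getattr(metrics, field_name), kind)}")
    for title, hist, fmt_key in [
        ("Pitch classes (% of playing time)", metrics.pitch_class_pct, str),
        ("Octave histogram (% of playing time)", metrics.octave_hist, str),
        ("Intensity histogram (% of playing time)", metrics.intensity_hist, str),
    ]:
        if not hist:
            continue
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        for key in hist:
            lines.append(f"  {fmt_key(key):<6s} {hist[key]:.1f}")
    return "\n".join(lines) + "\n"


def piano_roll_table(session: SessionRecord) -> pd.DataFrame:
    """One row per note interval: onset, offset, note name+octave,
    velocity and key color — the tabular twin of a piano-roll plot."""
    ivs = pair_events(session.events, t_end=session.t_end)
    return pd.DataFrame(
        [
            {
                "onset_s": iv.onset,
                "offset_s": iv.offset,
                "note": iv.note,
                "name": note_name(iv.note),
                "velocity": iv.velocity,
                "color": note_color(iv.note),
            }
            for iv in ivs
        ],
        columns=["onset_s", "offset_s", "note", "name", "velocity", "color"],
    )


def plot_piano_roll(sessions, labels=None, ax=None):
    """Piano-roll figure: time on the abscissa, keyboard on the ordinate;
    one color series per session (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if isinstance(sessions, SessionRecord):
        sessions = [sessions]
    labels = labels or [s.session_id for s in sessions]
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 5))
    colors = ["black", "red", "blue", "green"]
    for i, (s, lab) in enumerate(zip(sessions, labels)):
        table = piano_roll_table(s)
        c = colors[i % len(colors)]
        for _, row in table.iterrows():
            ax.hlines(row["note"], row["onset_s"], row["offset_s"],
                      color=c, lw=2)
        ax.plot([], [], color=c, label=lab)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("MIDI note")
    ax.legend()
    return ax


_ROW_LABELS = {
    "pct_playing_time": "% playing time",
    "pct_idle_time": "% idle time",
    "pct_start_time": "% start time",
    "pct_concurrent": "% concurrent",
    "total_session_min": "total (minutes)",
    "n_presses": "# of presses",
    "pct_keys_used": "% used",
    "presses_per_key": "presses per key",
    "play_per_key_s": "play per key (sec)",
    "pct_black_presses": "% black presses",
    "pct_white_presses": "% white presses",
    "intensity_avg": "intensity: average",
    "intensity_min": "intensity: lowest",
    "intensity_max": "intensity: highest",
    "intensity_most_used": "intensity: most used",
    "octave_avg": "octave: average",
    "octave_min": "octave: lowest",
    "octave_max": "octave: highest",
    "octave_most_used": "octave: most used",
    "cluster_instances": "# of instances",
    "cluster_max": "max pressed",
    "cluster_mode": "most pressed",
    "pct_time_cluster_mode": "% most played",
    "pct_diminuendo": "% diminuendo",
    "pct_crescendo": "% crescendo",
    "pct_same_intensity": "% same intensity",
    "pct_accelerando": "% accelerando",
    "pct_ritardando": "% ritardando",
    "pct_wb": "% white to black",
    "pct_bw": "% black to white",
    "pct_bb": "% black to black",
    "pct_ww": "% white to white",
}


def cohort_table_frame(
    aggregates: list[GroupAggregate],
    stats: pd.DataFrame | None = None,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Machine-readable cohort matrix: one row per parameter, columns
    mean/SEM per group plus the comparison p-value when supplied."""
    params = parameters or [
        p for p in SCALAR_FIELDS if p in aggregates[0].mean and p != "start_time_s"
    ]
    for agg in aggregates[1:]:
        if set(agg.mean) != set(aggregates[0].mean):
            raise ValueError("aggregates carry mismatched parameter sets")
    rows = []
    stat_by_param = (
        {r["parameter"]: r for _, r in stats.iterrows()} if stats is not None else {}
    )
    for p in params:
        row: dict = {"parameter": p, "label": _ROW_LABELS.get(p, p)}
        for agg in aggregates:
            row[f"{agg.label}_mean"] = agg.mean[p]
            row[f"{agg.label}_sem"] = agg.sem[p]
        if p in stat_by_param:
            row["p"] = stat_by_param[p]["p"]
            row["direction"] = stat_by_param[p]["direction"]
        rows.append(row)
    return pd.DataFrame(rows)


def _cell(mean: float, sem: float, stars: str = "") -> str:
    if mean is None or (isinstance(mean, float) and math.isnan(mean)):
        return "n/a"
    sem_txt = "0" if sem == 0 else f"{sem:.2g}"
    return f"{mean:.3g} ({sem_txt}){stars}"


def render_cohort_table(
    aggregates: list[GroupAggregate],
    stats: pd.DataFrame | None = None,
    parameters: list[str] | None = None,
    overall: GroupAggregate | None = None,
) -> str:
    """Parameter x group matrix of "mean (SEM)" cells.

    Stars (* p<.05, ** p<.01, *** p<.001) annotate the group with the
    larger mean, per the one-sided reading of the comparison.
    """
    frame = cohort_table_frame(aggregates, stats, parameters)
    cols = ([overall.label] if overall else []) + [a.label for a in aggregates]
    width = max(len(str(l)) for l in frame["label"]) + 2
    header = "Parameter".ljust(width) + "".join(f"{c:>22s}" for c in cols)
    lines = [header, "-" * len(header)]
    stat_by_param = (
        {r["parameter"]: r for _, r in stats.iterrows()} if stats is not None else {}
    )
    for _, row in frame.iterrows():
        p = row["parameter"]
        cells = []
        if overall:
            cells.append(_cell(overall.mean.get(p), overall.sem.get(p)))
        st = stat_by_param.get(p)
        for agg in aggregates:
            stars = ""
            if st is not None and st["direction"] == agg.label:
                stars = significance_stars(st["p"])
            cells.append(_cell(agg.mean[p], agg.sem[p], stars))
        lines.append(row["label"].ljust(width) + "".join(f"{c:>22s}" for c in cells))
    lines.append("")
    lines.append("Cells: mean (SEM).  * p < .05; ** p < .01; *** p < .001")
    return "\n".join(lines) + "\n"
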