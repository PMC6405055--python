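"""Per-session behavioral parameters: worked examples, percentage
identities, and recovery of configured tendencies from the generator."""

import math

import numpy as np
import pytest

from improvkit.io import SessionRecord
from improvkit.keyboard import DEFAULT_KEYBOARD, dynamics_level
from improvkit.metrics import (
    aggregate,
    compute_cluster_metrics,
    compute_concurrent_metric,
    compute_key_metrics,
    compute_profiles,
    compute_session_metrics,
    compute_time_metrics,
    compute_transition_metrics,
    metrics_frame,
)
from improvkit.synthetic import ImprovProfile, sample_cohort, sample_session, vary
from conftest import make_session


def test_time_metrics_direct_arithmetic():
    # one 63-s note in a 100-s session starting at 22.2 s
    session = make_session([(22.2, 85.2, 60, 80)], t_end=100.0)
    t = compute_time_metrics(session)
    assert t["pct_playing_time"] == pytest.approx(63.0)
    assert t["pct_idle_time"] == pytest.approx(37.0)
    assert t["start_time_s"] == pytest.approx(22.2)
    assert t["pct_start_time"] == pytest.approx(22.2)
    assert t["total_session_min"] == pytest.approx(100.0 / 60.0)


def test_time_metrics_empty_session_flags_start_missing():
    session = SessionRecord(session_id="e", events=[], t_end=10.0)
    t = compute_time_metrics(session)
    assert t["pct_playing_time"] == 0.0
    assert t["pct_idle_time"] == 100.0
    assert math.isnan(t["start_time_s"])


def test_time_metrics_full_length_note():
    session = make_session([(0, 10, 60, 80)], t_end=10.0)
    t = compute_time_metrics(session)
    assert t["pct_playing_time"] == pytest.approx(100.0)
    assert t["pct_start_time"] == pytest.approx(0.0)


def test_time_metrics_zero_length_session_rejected():
    session = SessionRecord(session_id="z", events=[], t0=0.0, t_end=0.0)
    with pytest.raises(ValueError):
        compute_time_metrics(session)


def test_concurrent_metric_two_keys_throughout_is_200():
    session = make_session([(0, 10, 60, 80), (0, 10, 64, 80)], t_end=10.0)
    assert compute_concurrent_metric(session) == pytest.approx(200.0)


def test_concurrent_metric_three_keys_throughout_is_300():
    session = make_session(
        [(0, 10, 60, 80), (0, 10, 64, 80), (0, 10, 67, 80)], t_end=10.0
    )
    assert compute_concurrent_metric(session) == pytest.approx(300.0)


def test_concurrent_metric_partial_overlap():
    # A(0-2), B(1-3): integral 4 over union 3
    session = make_session([(0, 2, 60, 80), (1, 3, 62, 80)], t_end=3.0)
    assert compute_concurrent_metric(session) == pytest.approx(400.0 / 3.0)


def test_concurrent_metric_no_notes_is_missing():
    session = SessionRecord(session_id="e", events=[], t_end=10.0)
    assert math.isnan(compute_concurrent_metric(session))


def test_key_metrics_counts_and_colors():
    session = make_session(
        [(0, 1, 60, 80), (1.5, 2.5, 60, 80), (3, 4, 61, 80)], t_end=4.0
    )
    k = compute_key_metrics(session)
    assert k["n_presses"] == 3
    assert k["presses_per_key"] == pytest.approx(1.5)
    assert k["pct_black_presses"] == pytest.approx(100.0 / 3.0)
    assert k["pct_white_presses"] == pytest.approx(200.0 / 3.0)
    assert k["pct_keys_used"] == pytest.approx(100.0 * 2 / 76)


def test_key_metrics_play_per_key_is_mean_duration():
    session = make_session([(0, 1, 60, 80), (2, 5, 62, 80)], t_end=5.0)
    assert compute_key_metrics(session)["play_per_key_s"] == pytest.approx(2.0)


def test_key_metrics_no_presses_flagged():
    session = SessionRecord(session_id="e", events=[], t_end=5.0)
    k = compute_key_metrics(session)
    assert k["n_presses"] == 0
    assert math.isnan(k["presses_per_key"])


def test_profiles_single_note_occupies_whole_histogram():
    session = make_session([(0, 2, 60, 64)], t_end=2.0)
    p = compute_profiles(session)
    assert p["octave_hist"][4] == pytest.approx(100.0)
    assert p["intensity_hist"][dynamics_level(64)] == pytest.approx(100.0)
    assert p["pitch_class_pct"]["C"] == pytest.approx(100.0)


def test_profiles_pitch_class_duration_weights():
    session = make_session([(0, 2, 60, 80), (2, 3, 67, 80)], t_end=3.0)
    p = compute_profiles(session)
    assert p["pitch_class_pct"]["C"] == pytest.approx(200.0 / 3.0)
    assert p["pitch_class_pct"]["G"] == pytest.approx(100.0 / 3.0)


def test_profiles_min_max_and_tie_breaks_to_lower_level():
    session = make_session([(0, 1, 60, 30), (1, 2, 60, 120)], t_end=2.0)
    p = compute_profiles(session)
    assert p["intensity_min"] == dynamics_level(30)
    assert p["intensity_max"] == dynamics_level(120)
    assert p["intensity_most_used"] == dynamics_level(30)  # equal durations


def test_profiles_press_weighted_mode_variant():
    # two short presses at level(30), one long press at level(120)
    session = make_session(
        [(0, 0.1, 60, 30), (0.2, 0.3, 60, 30), (1, 5, 60, 120)], t_end=5.0
    )
    duration_mode = compute_profiles(session)["intensity_most_used"]
    press_mode = compute_profiles(session, duration_weighted_mode=False)[
        "intensity_most_used"
    ]
    assert duration_mode == dynamics_level(120)
    assert press_mode == dynamics_level(30)


def test_cluster_metrics_segment_enumeration():
    session = make_session([(0, 2, 60, 80), (1, 3, 62, 80)], t_end=3.0)
    c = compute_cluster_metrics(session)
    assert c["cluster_instances"] == 3
    assert c["cluster_max"] == 2
    assert c["cluster_mode"] == 1
    assert c["pct_time_cluster_mode"] == pytest.approx(200.0 / 3.0)


def test_cluster_metrics_single_note():
    session = make_session([(0, 1, 60, 80)], t_end=1.0)
    c = compute_cluster_metrics(session)
    assert (c["cluster_instances"], c["cluster_max"], c["cluster_mode"]) == (1, 1, 1)
    assert c["pct_time_cluster_mode"] == pytest.approx(100.0)


def test_cluster_metrics_above_ten_keys_reportable():
    session = make_session([(0, 1, 50 + k, 80) for k in range(11)], t_end=1.0)
    assert compute_cluster_metrics(session)["cluster_max"] == 11


def test_transition_metrics_velocity_pairs():
    session = make_session(
        [(0, 0.5, 60, 50), (1, 1.5, 60, 60), (2, 2.5, 60, 60)], t_end=3.0
    )
    t = compute_transition_metrics(session)
    assert t["pct_crescendo"] == pytest.approx(50.0)
    assert t["pct_same_intensity"] == pytest.approx(50.0)
    assert t["pct_diminuendo"] == pytest.approx(0.0)


def test_transition_metrics_tempo_tie_counts_as_ritardando():
    session = make_session(
        [(0, 0.5, 60, 80), (1, 1.5, 60, 80), (3, 3.5, 60, 80)], t_end=4.0
    )
    t = compute_transition_metrics(session)
    assert t["pct_ritardando"] == pytest.approx(100.0)
    assert t["pct_accelerando"] == pytest.approx(0.0)


def test_transition_metrics_color_pairs():
    session = make_session(
        [(0, 0.5, 60, 80), (1, 1.5, 61, 80), (2, 2.5, 62, 80)], t_end=3.0
    )
    t = compute_transition_metrics(session)
    assert t["pct_wb"] == pytest.approx(50.0)
    assert t["pct_bw"] == pytest.approx(50.0)
    assert t["pct_ww"] == 0.0
    assert t["pct_bb"] == 0.0


def test_transition_metrics_insufficient_presses_flagged():
    session = make_session([(0, 1, 60, 80)], t_end=1.0)
    t = compute_transition_metrics(session)
    assert math.isnan(t["pct_crescendo"])
    assert math.isnan(t["pct_accelerando"])


# ---------------------------------------------------------------------------
# full-session invariants


def assert_percentage_identities(m):
    assert m.pct_playing_time + m.pct_idle_time == pytest.approx(100.0)
    if m.n_presses > 0:
        assert m.pct_black_presses + m.pct_white_presses == pytest.approx(100.0)
        assert sum(m.pitch_class_pct.values()) == pytest.approx(100.0)
        assert sum(m.octave_hist.values()) == pytest.approx(100.0)
        assert sum(m.intensity_hist.values()) == pytest.approx(100.0)
        assert m.pct_concurrent >= 100.0 - 1e-9
        assert m.cluster_max >= m.cluster_mode >= 1
    if not math.isnan(m.pct_crescendo):
        assert m.pct_crescendo + m.pct_diminuendo + m.pct_same_intensity == pytest.approx(100.0)
        assert m.pct_ww + m.pct_wb + m.pct_bw + m.pct_bb == pytest.approx(100.0)
    if not math.isnan(m.pct_accelerando):
        assert m.pct_accelerando + m.pct_ritardando == pytest.approx(100.0)


def test_percentage_identities_hold_on_seeded_synthetic_sessions():
    profile = ImprovProfile()
    for seed in range(200):
        m = compute_session_metrics(sample_session(profile, seed=seed))
        assert_percentage_identities(m)


def test_empty_session_metrics_all_press_fields_missing():
    m = compute_session_metrics(SessionRecord(session_id="e", events=[], t_end=5.0))
    assert m.pct_playing_time == 0.0
    assert m.n_presses == 0
    assert math.isnan(m.intensity_avg)
    assert math.isnan(m.pct_concurrent)


def test_concurrent_is_exactly_100_without_overlap():
    session = make_session([(0, 1, 60, 80), (2, 3, 62, 80)], t_end=3.0)
    assert compute_concurrent_metric(session) == pytest.approx(100.0)


def test_duration_scale_invariance_of_weighted_summaries():
    base = [(0, 1, 60, 30), (2, 4, 64, 90), (5, 5.5, 61, 70)]
    doubled = [(2 * a, 2 * b, n, v) for a, b, n, v in base]
    m1 = compute_session_metrics(make_session(base, t_end=6.0))
    m2 = compute_session_metrics(make_session(doubled, t_end=12.0))
    assert m1.intensity_avg == pytest.approx(m2.intensity_avg)
    assert m1.octave_avg == pytest.approx(m2.octave_avg)
    assert m1.intensity_most_used == m2.intensity_most_used
    assert m1.octave_most_used == m2.octave_most_used


def test_raising_cluster_size_raises_mean_concurrency():
    means = []
    for sizes, probs in [((1,), (1.0,)), ((2,), (1.0,)), ((4,), (1.0,))]:
        profile = vary(ImprovProfile(), cluster_sizes=sizes, cluster_probs=probs)
        vals = [
            compute_session_metrics(sample_session(profile, seed=s)).pct_concurrent
            for s in range(50)
        ]
        means.append(np.nanmean(vals))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_identical_sessions_sem_zero():
    session = make_session([(0, 1, 60, 80), (1, 2, 62, 70)], t_end=2.0)
    sessions = []
    for i in range(4):
        s = make_session([(0, 1, 60, 80), (1, 2, 62, 70)], session_id=f"s{i}",
                         t_end=2.0, task="ugly")
        sessions.append(s)
    frame = metrics_frame(sessions)
    (agg,) = aggregate(frame, grouping="task")
    ref = compute_session_metrics(session)
    assert agg.mean["pct_playing_time"] == pytest.approx(ref.pct_playing_time)
    assert agg.sem["pct_playing_time"] == pytest.approx(0.0)


def test_aggregate_sem_from_two_values():
    import pandas as pd

    frame = pd.DataFrame(
        {"pct_playing_time": [1.0, 3.0], "task": ["ugly", "ugly"]}
    )
    (agg,) = aggregate(frame, grouping="task", parameters=["pct_playing_time"])
    assert agg.mean["pct_playing_time"] == pytest.approx(2.0)
    assert agg.sem["pct_playing_time"] == pytest.approx(1.0)


def test_valence_grouping_collapses_tasks():
    import pandas as pd

    frame = pd.DataFrame(
        {
            "task": ["ugly", "negative", "beautiful", "positive"],
            "pct_playing_time": [1.0, 2.0, 3.0, 4.0],
        }
    )
    aggs = aggregate(frame, grouping="valence", parameters=["pct_playing_time"])
    labels = {a.label: a for a in aggs}
    assert set(labels) == {"negative-valence", "positive-valence"}
    assert labels["negative-valence"].mean["pct_playing_time"] == pytest.approx(1.5)
    assert labels["positive-valence"].mean["pct_playing_time"] == pytest.approx(3.5)


def test_session_length_quintile_labels_are_cohort_relative():
    import pandas as pd

    from improvkit.metrics import DURATION_LABELS, session_length_labels

    frame = pd.DataFrame({"total_session_min": np.linspace(0.2, 3.0, 25)})
    labels = session_length_labels(frame)
    assert list(labels.value_counts()[list(DURATION_LABELS)]) == [5] * 5
    assert labels.iloc[0] == "extremely short"
    assert labels.iloc[-1] == "extremely long"


def test_age_split_over_median_is_old():
    import pandas as pd

    frame = pd.DataFrame(
        {"age": [20, 28, 30, 40], "pct_playing_time": [1, 2, 3, 4]}
    )
    aggs = aggregate(frame, grouping="age", parameters=["pct_playing_time"])
    labels = {a.label: a.n for a in aggs}
    # median 29: 20 and 28 young, 30 and 40 old
    assert labels == {"young": 2, "old": 2}
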