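"""Quantify one improvisation and print its textual report.

Builds a tiny twelve-second session by hand (a soft start, a loud
three-note cluster, a closing run), computes every per-session
parameter, and renders the comprehensive report.  Percentages of session
time (playing/idle/start), concurrency (>=100%: 200% means two keys were
held in parallel on average), key/cluster use and press-to-press
transition shares are all derived from the raw on/off event stream.
"""

from improvkit import RawEvent, SessionRecord, compute_session_metrics, render_session_report

events = [
    # a hesitant opening note
    RawEvent(2.0, "on", 64, 40), RawEvent(3.5, "off", 64),
    # a held three-note cluster (C4-E4-G4), struck hard
    RawEvent(4.0, "on", 60, 110), RawEvent(4.01, "on", 64, 105),
    RawEvent(4.02, "on", 67, 108),
    RawEvent(7.0, "off", 60), RawEvent(7.0, "off", 64), RawEvent(7.0, "off", 67),
    # a quick descending run with a black key
    RawEvent(8.0, "on", 66, 70), RawEvent(8.4, "off", 66),
    RawEvent(8.5, "on", 62, 60), RawEvent(9.0, "off", 62),
]
session = SessionRecord(session_id="demo", events=events, t0=0.0, t_end=12.0)

metrics = compute_session_metrics(session)
print(render_session_report(metrics))
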