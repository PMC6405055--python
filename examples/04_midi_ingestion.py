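"""Ingest a Standard MIDI File and inspect the note stream.

Writes a small two-chord SMF (with a mid-file tempo change to show the
tempo-map conversion), reads it back into a session, and prints the
piano-roll table plus the Idle/Playing state trace.
"""

import tempfile
from pathlib import Path

from improvkit import read_smf, state_trace
from improvkit.reporting import piano_roll_table
from improvkit.smf import write_smf_file

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.mid"
    # 480 ticks/quarter; 120 BPM then 60 BPM from tick 960
    write_smf_file(
        path,
        events=[
            (0, "on", 60, 90), (0, "on", 64, 85),
            (480, "off", 60, 0), (480, "off", 64, 0),
            (960, "on", 55, 70), (1440, "off", 55, 0),
        ],
        tempo_changes=[(0, 500_000), (960, 1_000_000)],
    )
    (session,) = read_smf(path)

print("piano roll (times in seconds after tempo-map conversion):")
print(piano_roll_table(session).to_string(index=False))

trace = state_trace(session)
print("\nstate trace (Playing while any key is held):")
for t, state in trace.states:
    print(f"  t={t:5.2f}s  {state}")
print(f"max cluster size: {trace.max_cluster}")
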