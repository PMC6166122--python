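"""Generate one synthetic driving session and write it to disk.

A trip is ~3 minutes of highly automated driving with three approaches to
a lead truck; the participant reports discomfort with a graded handset
lever.  The generator emits every sensor stream at its native rate.
"""

import tempfile
from pathlib import Path

import discomfortlab as dl

channels, events, kin = dl.simulate_trip(seed=42)

print(f"trip duration: {kin.time_s[-1]:.1f} s, minimum gap: {kin.gap_m.min():.2f} m")
print(f"brake onsets at: {[round(t, 1) for t in kin.brake_onsets_s]} s")
print(f"{len(channels)} channels, {events['blinks'].onsets_s.size} blink events")
for name in ("handset", "hr", "pupil_left", "shoulder_z", "seat_back"):
    ch = channels[name]
    print(f"  {name:12s} {ch.rate_hz:5.0f} Hz  {ch.values.size:6d} samples [{ch.unit}]")

out = Path(tempfile.mkdtemp()) / "p00_s1"
dl.write_session(out, channels, events, participant="p00", session="s1", seed=42)
print(f"session written to {out} (one CSV per channel + manifest.yaml)")

# The minimum gap equals the scenario's configured 4.2 m: the braking
# controller nulls the closing speed exactly at that distance.
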