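"""Generate one synthetic auditory-intensity session and inspect its design.

The generator emulates a graded-intensity experiment: 5 tone-train
intensities x 7 trials, each train 20 tones of 1003 Hz followed by 30 s of
rest, with ECG/PPG/EDA and dual-wavelength fNIRS channels plus the ground
truth of everything injected.
"""

import numpy as np

from audiophys import SessionConfig, synth_session

session = synth_session(SessionConfig(seed=1))
ev = session.events

print(f"session duration: {session.config.duration_s:.0f} s")
print(f"trials: {len(ev)} ({np.unique(ev.labels).size} intensities, "
      f"{(ev.labels == 94.5).sum()} trials each)")
print(f"ECG: {session.ecg.n} samples at {session.ecg.fs:g} Hz; "
      f"{session.truth.r_times.size} true R peaks")
print(f"EDA: {len(session.truth.scr_events)} true skin-conductance responses")
print(f"fNIRS: {len(session.fnirs)} channel-wavelength series at "
      f"{session.config.fs_fnirs:g} Hz")
print("\nFirst five scheduled trials (onset s, dBA, trial#):")
print(session.events.df.head().to_string(index=False))
# The onsets advance by train duration (10 s) + rest (30 s); the intensity
# order is a seeded random permutation, balanced across intensities.
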