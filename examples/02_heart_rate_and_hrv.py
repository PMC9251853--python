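"""R-peak detection, event-locked heart rate, and HRV metrics.

Detects QRS complexes with the Pan-Tompkins chain, converts intervals to
an instantaneous heart-rate series, epochs it around each tone train, and
computes time- and frequency-domain HRV over the 50 s post-stimulus span.
"""

import numpy as np

from audiophys import (SessionConfig, synth_session, filter_ecg,
                       detect_r_peaks, hr_series, hrv_time, hrv_spectrum,
                       epoch_baseline, window_mean)

session = synth_session(SessionConfig(seed=2))
beats = detect_r_peaks(filter_ecg(session.ecg))
truth = session.truth.r_times
err_ms = 1000 * np.abs(truth[:, None] - beats.r_times[None, :]).min(axis=1)
print(f"beats: {beats.n} detected / {truth.size} true "
      f"(median timing error {np.median(err_ms):.1f} ms)")

hr = hr_series(beats, fs_out=4.0)
ep = epoch_baseline(hr, session.events, window=(-5, 50), baseline=(-5, 0))
tw1 = window_mean(ep, (1.0, 3.0)).groupby("intensity")["value"].mean()
print("\nbaseline-subtracted HR, 1-3 s window, by intensity (bpm):")
print(tw1.round(2).to_string())
# The generator injects a -3 bpm dip in the first 3 s at 94.5 dBA only;
# the other intensities should hover near zero.

onset = session.events.onsets[0]
td = hrv_time(beats, window=(onset, onset + 50.0))
bp = hrv_spectrum(beats, window=(onset, onset + 50.0))
print(f"\nfirst-trial HRV: RMSSD {td.rmssd:.1f} ms, SDNN {td.sdnn:.1f} ms, "
      f"LFnu {bp.lfnu:.1f}, HFnu {bp.hfnu:.1f} "
      f"(low-res flag: {bp.low_resolution})")
# A 50 s window barely resolves the 0.04 Hz LF edge, hence the flag.
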