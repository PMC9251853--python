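"""Pulse-wave amplitude, spectral bands, and pulse transit time.

The rectified band-passed pulse tracks peripheral blood volume; the
Lomb-Scargle bands of the raw 12 s post-stimulus segment index vascular
tone; and PTT - the R-peak to pulse-arrival delay - shortens under
vasoconstriction.
"""

from audiophys import (SessionConfig, synth_session, filter_ecg, filter_ppg,
                       detect_r_peaks, absolute_ppg_epochs, ppg_lomb_bands,
                       compute_ptt, ptt_epochs, window_mean)

session = synth_session(SessionConfig(seed=3))
beats = detect_r_peaks(filter_ecg(session.ecg))
ppg_f = filter_ppg(session.ppg)

ep = absolute_ppg_epochs(ppg_f, session.events)
amp = window_mean(ep, (4.0, 8.0)).groupby("intensity")["value"].mean()
print("mean |PPG| change, 4-8 s window, by intensity:")
print(amp.round(4).to_string())
# The 20% amplitude drop injected at 94.5 dBA appears as a negative
# deflection of about -0.2 * 2A/pi; other intensities stay near zero.

bands = ppg_lomb_bands(session.ppg, session.events)
print("\nLomb LFnu by intensity (12 s segments, under-resolved LF flagged "
      f"{bands['low_resolution'].iloc[0]}):")
print(bands.groupby("intensity")["lfnu"].mean().round(1).to_string())

ptt = compute_ptt(beats, ppg_f)
_, tab = ptt_epochs(ptt, session.events)
print("\nPTT change (ms) by intensity and window:")
print(tab.groupby(["tw", "intensity"])["value"].mean().round(1).unstack()
      .to_string())
# The injected -10 ms transit-time drop at the highest intensity shows up
# in both the 6-8 s and 8-10 s windows.
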