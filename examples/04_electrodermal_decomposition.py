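"""Continuous decomposition of electrodermal activity.

Splits the skin-conductance signal into a slow tonic level and a phasic
component driven by sparse sudomotor impulses (Bateman-kernel
deconvolution), then quantifies stimulus-locked responses in the 1-5 s
window with a 0.01 uS amplitude threshold.
"""

from audiophys import SessionConfig, synth_session, cda_decompose, scr_metrics

session = synth_session(SessionConfig(seed=4))
res = cda_decompose(session.eda)
print(f"optimized Bateman taus: rise {res.params.tau_rise:.2f} s, "
      f"decay {res.params.tau_decay:.2f} s")
print(f"detected SCRs: {len(res.scrs)} "
      f"(ground truth: {len(session.truth.scr_events)})")

tab = scr_metrics(res, session.events)
print("\nper-intensity phasic metrics (trial means):")
print(tab.groupby("intensity")[["AmpSum", "nSCR", "SCR", "PhasicMax"]]
      .mean().round(3).to_string())
# SCR probability and amplitude are identical across intensities in the
# default conditions, so no intensity gradient is expected here - the
# electrodermal channel acts as the built-in negative control.
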