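"""The fNIRS chain: raw intensities to ROI chromophore epochs.

Prunes bad channels, converts to optical density, removes motion via
wavelet outlier rejection, band-passes 0.01-0.5 Hz, applies the modified
Beer-Lambert law (DPF 6/5 at 760/850 nm), block-averages, collapses
channels into auditory and visual ROIs, and finally regresses the visual
ROI out of the auditory channels to suppress the shared global signal.
"""

import numpy as np

from audiophys import SessionConfig, synth_session
from audiophys import hemodynamics as hd

session = synth_session(SessionConfig(seed=5))
hb = hd.process_channels(session.fnirs, session.montage)
print(f"retained channels: {len(hb.channels())}")

for tag, series in (("unregressed", hb),
                    ("visual-regressed", hd.regress_global(hb, session.montage))):
    ep = hd.block_average(series, session.events)
    roi = hd.roi_collapse(ep, session.montage)
    wm = hd.windowed_means({k: v for k, v in roi.items()
                            if not (tag.startswith("visual") and k == "VSC")})
    hbo = wm[(wm.chromophore == "HbO") & (wm.tw == "TW2")]
    print(f"\n{tag} dHbO, 13-23 s window, by intensity (uM):")
    print(hbo.groupby("intensity")["value"].mean().round(3).to_string())
# The generator injects a -0.2 uM global HbO decrease at 94.5 dBA: it is
# plainly visible before regression and largely removed after, because the
# injection rides on the global component shared with the visual channels.
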