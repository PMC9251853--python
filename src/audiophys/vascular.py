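"""PPG conditioning, amplitude epochs, spectral bands, and pulse transit time.

The absolute-amplitude metric rectifies the 0.2–5 Hz band-passed pulse
wave, epochs it around each tone-train onset (−5..50 s, 5 s baseline), and
summarizes the 4–8 s window.  The spectral metric takes the *unfiltered*
12 s post-stimulus segment and integrates a Lomb–Scargle periodogram into
LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) bands with Task-Force-style
normalized units.  Pulse transit time is the delay from each R peak to the
steepest upslope of the following pulse, searched in a 100–600 ms
physiological window.

The 12 s segments under-resolve the LF band lower edge; band powers from
them carry a ``low_resolution`` flag rather than being refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BandPower, EpochSet, EventTable, Signal, band_power, \
    epoch_baseline, window_mean
from .cardiac import BeatSeries

PPG_EDGES = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
PTT_RANGE_MS = (100.0, 600.0)


@dataclass
class PttSeries:
    """Beat-wise transit times (ms) with quality flags."""

    beat_times: np.ndarray
    ptt_ms: np.ndarray
    flags: np.ndarray

    def good(self) -> tuple[np.ndarray, np.ndarray]:
        ok = ~self.flags
        return self.beat_times[ok], self.ptt_ms[ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beat_time_s": self.beat_times,
                             "ptt_ms": self.ptt_ms,
                             "flag": self.flags.astype(int)})


def filter_ppg(ppg: Signal, band: tuple = (0.2, 5.0), order: int = 4) -> Signal:
    """Zero-phase 0.2–5 Hz band-pass of the pulse wave."""
    nyq = ppg.fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"fs={ppg.fs} too low for band {band}")
    sos = sps.butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass",
                     output="sos")
    return ppg.copy_with(sps.sosfiltfilt(sos, ppg.values))


def absolute_ppg_epochs(ppg_filtered: Signal, events: EventTable,
                        window: tuple = (-5.0, 50.0),
                        baseline: tuple = (-5.0, 0.0)) -> EpochSet:
    """Rectify the filtered pulse wave and epoch it with baseline removal.

    The rectified mean of a sinusoid of amplitude A is 2A/π, so a constant
    pulse amplitude yields near-zero epochs and an amplitude drop appears
    as a negative deflection.
    """
    rect = ppg_filtered.copy_with(np.abs(ppg_filtered.values))
    return epoch_baseline(rect, events, window=window, baseline=baseline)


def lomb_psd(t: np.ndarray, x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Lomb–Scargle periodogram of a mean-subtracted segment.

    Scaled as a one-sided density against the segment's mean sampling
    rate, so band integrals are comparable across segments; on even
    sampling at Fourier frequencies it coincides with the classical
    periodogram.
    """
    x = x - np.mean(x)
    if np.ptp(x) < 1e-15:
        return np.zeros_like(freqs)
    pg = sps.lombscargle(t, x, 2 * np.pi * freqs)
    fs_eff = (x.size - 1) / (t[-1] - t[0])
    return pg * 2.0 / fs_eff


def ppg_lomb_bands(ppg_raw: Signal, events: EventTable,
                   window_s: float = 12.0,
                   freq_grid: tuple = (0.01, 0.5, 0.005),
                   edges: dict = None) -> pd.DataFrame:
    """Per-trial Lomb–Scargle band powers of the raw post-stimulus pulse.

    Returns one row per event with absolute LF/HF, LFnu, HFnu, LF/HF; an
    all-constant segment yields zero powers and missing normalized units.
    Rows carry ``low_resolution=True`` because a 12 s segment cannot
    resolve the 0.04 Hz band edge.
    """
    edges = edges or PPG_EDGES
    freqs = np.arange(*freq_grid)
    rows = []
    for onset, lab, tr in zip(events.onsets, events.labels, events.trials):
        i0 = int(round((onset - ppg_raw.t0) * ppg_raw.fs))
        i1 = i0 + int(round(window_s * ppg_raw.fs))
        if i0 < 0 or i1 > ppg_raw.n:
            warnings.warn(f"event at {onset:.1f}s outside recording, skipped")
            continue
        seg = ppg_raw.values[i0:i1]
        t = np.arange(seg.size) / ppg_raw.fs
        psd = lomb_psd(t, seg, freqs)
        bp = band_power(freqs, psd, edges=edges)
        rows.append((lab, tr, bp.lf, bp.hf, bp.lfnu, bp.hfnu, bp.lf_hf))
    df = pd.DataFrame(rows, columns=["intensity", "trial", "lf", "hf",
                                     "lfnu", "hfnu", "lf_hf"])
    df["low_resolution"] = window_s < 1.0 / edges["lf"][0]
    return df


def compute_ptt(beats: BeatSeries, ppg_filtered: Signal,
                search_ms: tuple = PTT_RANGE_MS,
                fiducial: str = "upslope",
                min_slope_frac: float = 0.25) -> PttSeries:
    """Beat-wise pulse transit time.

    For each unflagged R peak the pulse-arrival fiducial is located in the
    ``search_ms`` window after the peak: the time of maximum first
    derivative (default), the pulse peak, or the pulse foot (minimum
    before the upslope).  Beats whose best upslope is weaker than
    ``min_slope_frac`` of the across-beat median — a missing or corrupted
    pulse — are flagged.
    """
    good = ~beats.flags
    if not good.any():
        raise ValueError("no unflagged beats")
    v = ppg_filtered.values
    dv = np.gradient(v) * ppg_filtered.fs
    lo_off = int(round(search_ms[0] / 1000.0 * ppg_filtered.fs))
    hi_off = int(round(search_ms[1] / 1000.0 * ppg_filtered.fs))
    times, ptts, slopes = [], [], []
    for tb in beats.r_times[good]:
        i = int(round((tb - ppg_filtered.t0) * ppg_filtered.fs))
        lo, hi = i + lo_off, min(i + hi_off, v.size)
        if lo >= hi or lo < 0:
            times.append(tb), ptts.append(np.nan), slopes.append(0.0)
            continue
        j = lo + int(np.argmax(dv[lo:hi]))
        if fiducial == "peak":
            k = float(j + int(np.argmax(v[j:hi]))) if j < hi else float(j)
        elif fiducial == "foot":
            k = float(lo + int(np.argmin(v[lo:j + 1])))
        else:
            # sub-sample parabolic refinement of the derivative peak
            k = float(j)
            if 0 < j < dv.size - 1:
                y0, y1, y2 = dv[j - 1], dv[j], dv[j + 1]
                denom = y0 - 2 * y1 + y2
                if abs(denom) > 1e-12:
                    k += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        times.append(tb)
        ptts.append((k / ppg_filtered.fs + ppg_filtered.t0 - tb) * 1000.0)
        slopes.append(dv[j])
    times, ptts, slopes = map(np.asarray, (times, ptts, slopes))
    med = np.median(slopes[slopes > 0]) if np.any(slopes > 0) else 0.0
    flags = (~np.isfinite(ptts) | (slopes < min_slope_frac * med)
             | (ptts < search_ms[0] - 1e-9) | (ptts > search_ms[1] + 1e-9))
    return PttSeries(beat_times=times, ptt_ms=ptts, flags=flags)


def ptt_epochs(ptt: PttSeries, events: EventTable, fs_grid: float = 10.0,
               window: tuple = (-5.0, 50.0), baseline: tuple = (-5.0, 0.0),
               windows: tuple = ((6.0, 8.0), (8.0, 10.0))
               ) -> tuple[EpochSet, pd.DataFrame]:
    """Interpolate beat-wise PTT to a uniform grid, epoch, and summarize.

    Flagged beats are excluded from the interpolation.  Returns the epochs
    and a long table (intensity, trial, tw, value) with the mean over each
    analysis window (defaults 6–8 and 8–10 s).
    """
    tb, vals = ptt.good()
    if tb.size < 2:
        raise ValueError("need at least 2 unflagged PTT values")
    grid = np.arange(tb[0], tb[-1], 1.0 / fs_grid)
    interp = np.interp(grid, tb, vals)
    sig = Signal(fs=fs_grid, values=interp, t0=float(grid[0]), unit="ms",
                 label="PTT")
    ep = epoch_baseline(sig, events, window=window, baseline=baseline)
    rows = []
    for k, win in enumerate(windows, start=1):
        tab = window_mean(ep, win)
        tab["tw"] = f"TW{k}"
        rows.append(tab)
    return ep, pd.concat(rows, ignore_index=True)
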