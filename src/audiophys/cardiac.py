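"""ECG conditioning, R-peak detection, and heart-rate-variability metrics.

R peaks are found with the Pan–Tompkins chain (band-pass, derivative,
squaring, moving-window integration, adaptive thresholding with a 200 ms
refractory period), and implausible inter-beat intervals (<300 or
>2000 ms) are flagged automatically in place of manual ectopic-beat
inspection.  Frequency-domain HRV interpolates the interval series with
cubic splines at 2 Hz, removes the constant level, applies a Hann window,
and integrates the FFT periodogram over the VLF (0–0.04 Hz), LF
(0.04–0.15 Hz), and HF (0.15–0.5 Hz) bands; an order-16 Burg
autoregressive spectrum is available as a method switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import BandPower, Signal, band_power

HRV_EDGES = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.5)}

IBI_MIN_MS = 300.0
IBI_MAX_MS = 2000.0


@dataclass
class BeatSeries:
    """R-peak times (s) with per-beat quality flags.

    ``ibis`` are the successive differences in ms; ``flags[i]`` is True when
    the interval *ending* at beat ``i+1`` (or the beat itself) is implausible
    and must be excluded from metrics.
    """

    r_times: np.ndarray
    flags: np.ndarray = None

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(self.r_times.size, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n(self) -> int:
        return self.r_times.size

    @property
    def ibis(self) -> np.ndarray:
        """All successive intervals in ms (length n−1)."""
        return np.diff(self.r_times) * 1000.0

    def good_ibis(self) -> tuple[np.ndarray, np.ndarray]:
        """(interval end-times, intervals ms) with flagged beats excluded."""
        ok = ~self.flags[:-1] & ~self.flags[1:]
        return self.r_times[1:][ok], self.ibis[ok]

    def to_frame(self):
        import pandas as pd
        ibi = np.concatenate(([np.nan], self.ibis))
        return pd.DataFrame({"r_time_s": self.r_times, "ibi_ms": ibi,
                             "flag": self.flags.astype(int)})


@dataclass
class HrvTimeDomain:
    rmssd: float
    sdnn: float
    n_beats: int


def filter_ecg(ecg: Signal, band: tuple = (0.5, 35.0), order: int = 4) -> Signal:
    """Zero-phase 0.5–35 Hz band-pass; length preserved."""
    nyq = ecg.fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"fs={ecg.fs} too low for band {band}")
    sos = sps.butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass",
                     output="sos")
    return ecg.copy_with(sps.sosfiltfilt(sos, ecg.values))


def _flag_implausible(r_times: np.ndarray) -> np.ndarray:
    flags = np.zeros(r_times.size, dtype=bool)
    ibis = np.diff(r_times) * 1000.0
    bad = (ibis < IBI_MIN_MS) | (ibis > IBI_MAX_MS)
    # an implausible interval taints the beat that closes it
    flags[1:][bad] = True
    return flags


def detect_r_peaks(ecg: Signal, refractory_s: float = 0.2) -> BeatSeries:
    """Pan–Tompkins QRS detection with adaptive thresholding.

    Stages: 5–15 Hz band-pass → derivative → squaring → 150 ms
    moving-window integration → adaptive signal/noise thresholds with a
    refractory period; detected peaks are refined to the local maximum of
    the band-passed ECG.  Implausible intervals are flagged, not removed.
    """
    if ecg.fs < 100:
        raise ValueError("R-peak detection needs fs >= 100 Hz")
    x = ecg.values - np.mean(ecg.values)
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG: no beats detected")
        return BeatSeries(r_times=np.empty(0))
    nyq = ecg.fs / 2.0
    sos = sps.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq],
                     btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * ecg.fs
    sq = deriv ** 2
    w = max(1, int(round(0.150 * ecg.fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refr = int(round(refractory_s * ecg.fs))
    # initial thresholds from the first 2 s
    init = mwi[:int(2 * ecg.fs)]
    spki = float(np.max(init)) * 0.6 if init.size else float(np.max(mwi)) * 0.6
    npki = float(np.mean(init)) * 0.5
    thr = npki + 0.25 * (spki - npki)
    peaks, _ = sps.find_peaks(mwi, distance=refr)
    accepted = []
    for p in peaks:
        if mwi[p] > thr:
            if accepted and p - accepted[-1] < refr:
                continue
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
        thr = npki + 0.25 * (spki - npki)
    if not accepted:
        warnings.warn("no QRS complexes above threshold")
        return BeatSeries(r_times=np.empty(0))
    # refine to the band-passed ECG maximum within +-50 ms
    half = int(round(0.05 * ecg.fs))
    r_idx = []
    for p in accepted:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r_idx.append(lo + int(np.argmax(bp[lo:hi])))
    r_idx = np.unique(r_idx)
    r_times = ecg.t0 + r_idx / ecg.fs
    return BeatSeries(r_times=r_times, flags=_flag_implausible(r_times))


def hr_series(beats: BeatSeries, fs_out: float) -> Signal:
    """Instantaneous HR (bpm = 60000/IBI) held on a uniform grid.

    Between beats i and i+1 the rate is the one defined by that interval
    (zero-order hold), so a step change in IBI appears as an HR step at
    the corresponding beat time.
    """
    t_ends, ibis = beats.good_ibis()
    if ibis.size < 1 or beats.n < 2:
        raise ValueError("need at least 2 unflagged beats")
    starts = t_ends - ibis / 1000.0
    hr = 60000.0 / ibis
    t0, t1 = starts[0], t_ends[-1]
    grid = np.arange(t0, t1, 1.0 / fs_out)
    idx = np.searchsorted(starts, grid, side="right") - 1
    idx = np.clip(idx, 0, hr.size - 1)
    return Signal(fs=fs_out, values=hr[idx], t0=float(grid[0]), unit="bpm",
                  label="HR")


def hrv_time(beats: BeatSeries, window: tuple | None = None) -> HrvTimeDomain:
    """RMSSD and SDNN of the unflagged intervals (optionally restricted to
    beats inside ``window`` seconds).

    RMSSD = sqrt(mean of squared successive differences); SDNN uses the
    n−1 sample standard deviation.
    """
    t_ends, ibis = beats.good_ibis()
    if window is not None:
        sel = (t_ends >= window[0]) & (t_ends < window[1])
        ibis = ibis[sel]
    if ibis.size < 2:
        raise ValueError("need at least 2 unflagged intervals (3 beats)")
    rmssd = float(np.sqrt(np.mean(np.diff(ibis) ** 2))) if ibis.size >= 2 else np.nan
    sdnn = float(np.std(ibis, ddof=1))
    return HrvTimeDomain(rmssd=rmssd, sdnn=sdnn, n_beats=int(ibis.size) + 1)


def hrv_spectrum(beats: BeatSeries, window: tuple | None = None,
                 fs_interp: float = 2.0, method: str = "fft",
                 ar_order: int = 16) -> BandPower:
    """Band powers of the interval spectrum.

    Cubic-spline interpolation of the IBI tachogram at ``fs_interp``,
    constant detrend, Hann window, FFT periodogram (or Burg AR spectrum),
    then VLF/LF/HF integration.  A window too short to resolve the LF
    lower edge is flagged ``low_resolution`` rather than refused.
    """
    t_ends, ibis = beats.good_ibis()
    if window is not None:
        sel = (t_ends >= window[0]) & (t_ends < window[1])
        t_ends, ibis = t_ends[sel], ibis[sel]
    if ibis.size < 4:
        raise ValueError("too few intervals for a spectrum")
    cs = CubicSpline(t_ends, ibis)
    grid = np.arange(t_ends[0], t_ends[-1], 1.0 / fs_interp)
    x = cs(grid) - np.mean(cs(grid))
    span = grid[-1] - grid[0]
    if method == "fft":
        win = np.hanning(x.size)
        xw = x * win
        # one-sided periodogram with window power compensation
        spec = np.abs(np.fft.rfft(xw)) ** 2 / (fs_interp * np.sum(win ** 2))
        spec[1:-1] *= 2.0
        freqs = np.fft.rfftfreq(x.size, 1.0 / fs_interp)
    elif method == "ar":
        freqs, spec = _burg_psd(x, ar_order, fs_interp)
    else:
        raise ValueError(f"unknown method {method!r}")
    bp = band_power(freqs, spec, edges=HRV_EDGES)
    bp.low_resolution = span < 1.0 / HRV_EDGES["lf"][0] if HRV_EDGES["lf"][0] > 0 else False
    return bp


def _burg_psd(x: np.ndarray, order: int, fs: float,
              nfreq: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Burg maximum-entropy AR spectrum (method switch for hrv_spectrum)."""
    a = np.array([1.0])
    f = x[1:].astype(float).copy()
    b = x[:-1].astype(float).copy()
    e = float(np.mean(x ** 2))
    for _ in range(order):
        denom = np.dot(f, f) + np.dot(b, b)
        if denom <= 0 or f.size == 0:
            break
        k = -2.0 * np.dot(f, b) / denom
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        e *= (1.0 - k ** 2)
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    freqs = np.linspace(0, fs / 2, nfreq)
    u = np.exp(-2j * np.pi * freqs / fs)
    denom = np.polyval(a[::-1], u)
    psd = e / fs / np.abs(denom) ** 2
    return freqs, psd
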