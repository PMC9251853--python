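"""Event-related skin conductance level and continuous decomposition.

The decomposition splits raw EDA into a slowly varying tonic level and a
phasic component driven by discrete sudomotor impulses: the measured
signal is modeled as tonic plus the convolution of a nonnegative driver
with the Bateman kernel ``exp(−t/τ_decay) − exp(−t/τ_rise)``.  The driver
is obtained by regularized frequency-domain deconvolution after removing
an initial tonic estimate (interpolation through smoothed local minima),
and the kernel time constants are grid-searched to minimize negative
driver mass plus driver roughness — the criterion that makes the driver
look like a sparse nonnegative impulse train.  Skin conductance responses
(SCRs) are driver impulses whose amplitude (impulse area, i.e. the phasic
rise it produces with the unit-peak kernel) reaches 0.01 μS; trial
metrics follow the standard phasic-analysis set (AmpSum, nSCR, mean
driver, PhasicMax in a 1–5 s post-stimulus window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, minimum_filter1d, percentile_filter

from .core import EpochSet, EventTable, Signal, epoch_baseline, window_mean


@dataclass
class CdaParams:
    """Decomposition settings: Bateman time constants, driver sampling
    rate, SCR amplitude threshold, and the post-stimulus response window."""

    tau_rise: float = 0.75
    tau_decay: float = 3.75
    driver_fs: float = 10.0
    amp_threshold_us: float = 0.01
    response_window: tuple = (1.0, 5.0)
    grid_rise: tuple = (0.5, 0.75, 1.0, 1.5)
    grid_decay: tuple = (2.0, 3.75, 6.0)
    reg: float = 0.02            # Tikhonov deconvolution regularizer

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.amp_threshold_us <= 0:
            raise ValueError("amplitude threshold must be positive")


@dataclass
class CdaResult:
    """tonic + phasic reconstructs the (resampled) input; the driver is the
    deconvolved sudomotor impulse series, and ``scrs`` the detected
    responses (onset/peak time, amplitude)."""

    tonic: Signal
    phasic: Signal
    driver: Signal
    scrs: pd.DataFrame
    params: CdaParams
    flagged: bool = False
    diagnostics: dict = field(default_factory=dict)


def scl_epochs(eda: Signal, events: EventTable,
               window: tuple = (-5.0, 50.0), baseline: tuple = (-5.0, 0.0),
               metric_window: tuple = (2.0, 8.0)
               ) -> tuple[EpochSet, pd.DataFrame]:
    """Event-related SCL: baseline-subtracted epochs and the 2–8 s mean."""
    ep = epoch_baseline(eda, events, window=window, baseline=baseline)
    return ep, window_mean(ep, metric_window)


def bateman_kernel(t: np.ndarray, tau_rise: float, tau_decay: float
                   ) -> np.ndarray:
    """Unit-peak Bateman kernel; zero for t < 0."""
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_decay)
                 - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0)
    tpk = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-tpk / tau_decay) - np.exp(-tpk / tau_rise)
    return k / peak


def _resample(eda: Signal, fs_out: float) -> Signal:
    if abs(eda.fs - fs_out) < 1e-9:
        return eda
    t_new = np.arange(eda.t0, eda.t0 + eda.duration - 1.0 / eda.fs, 1.0 / fs_out)
    # light anti-alias smoothing before decimation
    sigma = max(eda.fs / fs_out / 2.0, 1e-6)
    sm = gaussian_filter1d(eda.values, sigma)
    return Signal(fs=fs_out, values=np.interp(t_new, eda.times, sm),
                  t0=eda.t0, unit=eda.unit, label=eda.label)


def _smooth_detrended(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing around a fitted linear trend, so reflecting
    boundaries do not flatten a drifting tonic level at the edges."""
    i = np.arange(x.size, dtype=float)
    coef = np.polyfit(i, x, 1)
    trend = np.polyval(coef, i)
    return trend + gaussian_filter1d(x - trend, sigma)


def _initial_tonic(x: np.ndarray, fs: float, win_s: float = 20.0) -> np.ndarray:
    """Interpolation through smoothed local minima."""
    w = max(3, int(round(win_s * fs)))
    floor = minimum_filter1d(x, w)
    return gaussian_filter1d(floor, w / 2.0)


def _deconvolve(resid: np.ndarray, kernel: np.ndarray, dt: float,
                reg: float) -> np.ndarray:
    n = resid.size + kernel.size
    K = np.fft.rfft(kernel * dt, n)
    R = np.fft.rfft(resid, n)
    scale = np.max(np.abs(K)) ** 2
    D = R * np.conj(K) / (np.abs(K) ** 2 + reg * scale)
    return np.fft.irfft(D, n)[:resid.size]


def _convolve(driver: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    return np.convolve(driver, kernel)[:driver.size] * dt


def cda_decompose(eda: Signal, params: CdaParams | None = None,
                  optimize: bool = True) -> CdaResult:
    """Continuous decomposition of EDA into tonic and phasic components.

    Steps: resample to the driver rate, estimate an initial tonic floor,
    deconvolve the remainder by the Bateman kernel (Tikhonov-regularized,
    in the frequency domain), optionally grid-search the time constants
    for minimal negative-driver mass + roughness, rebuild the phasic
    component from the rectified driver, and set tonic = signal − phasic.
    """
    params = params or CdaParams()
    if eda.duration < 60.0:
        raise ValueError("decomposition needs at least 60 s of EDA")
    x_sig = _resample(eda, params.driver_fs)
    x = x_sig.values
    fs = params.driver_fs
    dt = 1.0 / fs
    tonic0 = _initial_tonic(x, fs)
    t_k = np.arange(0, 40.0, dt)

    def _decompose_once(resid: np.ndarray, tr: float, td: float) -> np.ndarray:
        k = bateman_kernel(t_k, tr, td)
        d = _deconvolve(resid, k, dt, params.reg)
        # the sudomotor driver is sparse: whatever slow baseline the
        # deconvolution assigns to it belongs to the tonic component
        base = gaussian_filter1d(
            percentile_filter(d, 20, size=int(30.0 * fs)), 5.0 * fs)
        return d - base

    def _score(tr: float, td: float) -> tuple[float, np.ndarray]:
        # first pass from the minima-floor tonic, then refine the tonic as
        # a smooth fit of (signal - phasic) and deconvolve once more: the
        # floor estimate under-shoots during SCR tails and would otherwise
        # inflate impulse areas
        k = bateman_kernel(t_k, tr, td)
        d = _decompose_once(x - tonic0, tr, td)
        phasic0 = _convolve(np.clip(d, 0, None), k, dt)
        tonic1 = _smooth_detrended(x - phasic0, 10.0 * fs)
        d = _decompose_once(x - tonic1, tr, td)
        neg = float(np.sum(np.clip(-d, 0, None)) * dt)
        rough = float(np.sum(np.diff(d) ** 2))
        return neg + 0.1 * rough, d

    best = (params.tau_rise, params.tau_decay)
    best_score, driver = _score(*best)
    if optimize:
        for tr in params.grid_rise:
            for td in params.grid_decay:
                if tr >= td:
                    continue
                s, d = _score(tr, td)
                if s < best_score:
                    best_score, driver, best = s, d, (tr, td)
    params = CdaParams(tau_rise=best[0], tau_decay=best[1],
                       driver_fs=params.driver_fs,
                       amp_threshold_us=params.amp_threshold_us,
                       response_window=params.response_window,
                       grid_rise=params.grid_rise, grid_decay=params.grid_decay,
                       reg=params.reg)
    kernel = bateman_kernel(t_k, *best)
    neg_mass = float(np.sum(np.clip(-driver, 0, None)) * dt)
    pos_mass = float(np.sum(np.clip(driver, 0, None)) * dt)
    flagged = pos_mass > 0 and neg_mass / max(pos_mass, 1e-12) > 0.5
    if flagged:
        warnings.warn("driver negativity remained high; defaults retained")
    driver_pos = np.clip(driver, 0.0, None)
    phasic = _convolve(driver_pos, kernel, dt)
    tonic = x - phasic
    scrs = _find_scrs(driver_pos, fs, x_sig.t0, params.amp_threshold_us)
    # impulses peaking in the truncated tail cannot be quantified reliably
    scrs = scrs[scrs["peak_s"] < x_sig.t0 + x_sig.duration - 5.0].reset_index(drop=True)
    mk = lambda v, u: Signal(fs=fs, values=v, t0=x_sig.t0, unit=u, label=eda.label)
    return CdaResult(tonic=mk(tonic, "uS"), phasic=mk(phasic, "uS"),
                     driver=mk(driver_pos, "uS/s"), scrs=scrs, params=params,
                     flagged=flagged,
                     diagnostics={"neg_mass": neg_mass, "pos_mass": pos_mass,
                                  "score": best_score})


def _find_scrs(driver: np.ndarray, fs: float, t0: float,
               threshold: float) -> pd.DataFrame:
    """Segment the nonnegative driver into impulses between near-zero
    valleys; amplitude = impulse area (μS), the phasic rise it produces."""
    dt = 1.0 / fs
    # absolute floor: a threshold-level SCR deconvolves to a driver peak of
    # roughly amp/width ~ 2*threshold uS/s, so slow sub-threshold ripple
    # never strings together into one spurious segment
    floor = max(0.05 * float(driver.max(initial=0.0)), threshold)
    active = driver > floor
    rows = []
    i = 0
    n = driver.size
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        seg = driver[i:j]
        amp = float(seg.sum() * dt)
        if amp >= threshold:
            pk = i + int(np.argmax(seg))
            rows.append((t0 + i * dt, t0 + pk * dt, amp))
        i = j
    return pd.DataFrame(rows, columns=["onset_s", "peak_s", "amplitude_us"])


def scr_metrics(result: CdaResult, events: EventTable,
                params: CdaParams | None = None,
                epoch_window: tuple = (-5.0, 50.0)) -> pd.DataFrame:
    """Per-trial phasic metrics in the post-stimulus response window.

    AmpSum: summed amplitudes of above-threshold SCRs whose onset falls in
    the window; nSCR: their count; SCR: mean phasic driver over the
    window; PhasicMax: maximum phasic activity; tonic_mean: mean tonic
    level over the trial epoch.  Empty windows yield zeros.
    """
    params = params or result.params
    lo, hi = params.response_window
    drv, pha, ton = result.driver, result.phasic, result.tonic
    rows = []
    for onset, lab, tr in zip(events.onsets, events.labels, events.trials):
        sel = result.scrs[(result.scrs["onset_s"] >= onset + lo)
                          & (result.scrs["onset_s"] < onset + hi)]
        i0 = int(round((onset + lo - drv.t0) * drv.fs))
        i1 = int(round((onset + hi - drv.t0) * drv.fs))
        i0c, i1c = max(i0, 0), min(i1, drv.n)
        dwin = drv.values[i0c:i1c]
        pwin = pha.values[i0c:i1c]
        e0 = max(int(round((onset + epoch_window[0] - ton.t0) * ton.fs)), 0)
        e1 = min(int(round((onset + epoch_window[1] - ton.t0) * ton.fs)), ton.n)
        rows.append((lab, tr,
                     float(sel["amplitude_us"].sum()), int(len(sel)),
                     float(dwin.mean()) if dwin.size else 0.0,
                     float(pwin.max()) if pwin.size else 0.0,
                     float(ton.values[e0:e1].mean()) if e1 > e0 else np.nan))
    return pd.DataFrame(rows, columns=["intensity", "trial", "AmpSum", "nSCR",
                                       "SCR", "PhasicMax", "tonic_mean"])
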