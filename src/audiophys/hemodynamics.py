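"""fNIRS processing chain: raw dual-wavelength intensities to ROI epochs.

The chain follows the conventional continuous-wave pipeline: channel
pruning on signal level and coefficient of variation, optical-density
conversion against the channel mean, wavelet-based motion correction
(IQR outlier rule on detail coefficients), 0.01–0.5 Hz band-pass,
residual-artifact masking, modified Beer–Lambert conversion to ΔHbO/ΔHbR
(DPF 6 at 760 nm and 5 at 850 nm, 3 cm source–detector distance), block
averaging, ROI collapse (left/right auditory cortex and a visual set),
and — in place of short-separation channels — regression of the visual
ROI time course out of each auditory channel to suppress the global
scalp/systemic component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .core import EpochSet, EventTable, Signal, epoch_baseline, window_mean

logger = logging.getLogger("audiophys")

ROIS = ("LAC", "RAC", "VSC")


@dataclass(frozen=True)
class Channel:
    source: int
    detector: int
    distance_cm: float = 3.0

    @property
    def name(self) -> str:
        return f"S{self.source}-D{self.detector}"


@dataclass
class Montage:
    """Source-detector channels, their wavelengths, and ROI assignment."""

    channels: list
    wavelengths: tuple = (760, 850)
    roi_map: dict = field(default_factory=dict)

    def __post_init__(self):
        for ch in self.channels:
            if ch.distance_cm <= 0:
                raise ValueError(f"{ch.name}: distance must be positive")
            if ch.name not in self.roi_map:
                raise ValueError(f"{ch.name}: no ROI assignment")

    def roi_channels(self, roi: str) -> list:
        return [ch for ch in self.channels if self.roi_map[ch.name] == roi]


def default_montage() -> Montage:
    """Desk-scale montage: 3 channels per auditory cortex, 2 visual."""
    chans = [Channel(s, s) for s in range(1, 9)]
    rois = ["LAC"] * 3 + ["RAC"] * 3 + ["VSC"] * 2
    return Montage(channels=chans,
                   roi_map={c.name: r for c, r in zip(chans, rois)})


@dataclass
class OpticalConstants:
    """Extinction coefficients (1/(mM·cm)) and differential pathlength factors.

    Values follow the standard compiled hemoglobin spectra used by
    continuous-wave fNIRS software; override for a different table.
    """

    extinction: dict = field(default_factory=lambda: {
        (760, "HbO"): 0.586, (760, "HbR"): 1.548,
        (850, "HbO"): 1.058, (850, "HbR"): 0.691,
    })
    dpf: dict = field(default_factory=lambda: {760: 6.0, 850: 5.0})

    def matrix(self, wavelengths: tuple) -> np.ndarray:
        return np.array([[self.extinction[(wl, "HbO")],
                          self.extinction[(wl, "HbR")]] for wl in wavelengths])


@dataclass
class HbSeries:
    """Per-channel chromophore concentration changes (μM) with artifact mask."""

    hbo: dict            # channel -> ndarray
    hbr: dict
    fs: float
    mask: dict = None    # channel -> bool ndarray (True = artifact)

    @property
    def hbt(self) -> dict:
        return {ch: self.hbo[ch] + self.hbr[ch] for ch in self.hbo}

    def channels(self) -> list:
        return list(self.hbo)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def prune_channels(raw: dict, level_range: tuple = (0.03, 2.5),
                   cv_percent: float = 17.0) -> list:
    """Retain channels whose mean level lies in ``level_range`` at both
    wavelengths and whose coefficient of variation stays below the cutoff."""
    names = sorted({ch for ch, _ in raw})
    kept = []
    for ch in names:
        ok = True
        for (name, wl), sig in raw.items():
            if name != ch:
                continue
            m = float(np.mean(sig.values))
            cv = 100.0 * float(np.std(sig.values)) / m if m > 0 else np.inf
            if not (level_range[0] <= m <= level_range[1]) or cv > cv_percent:
                ok = False
        if ok:
            kept.append(ch)
        else:
            logger.info("pruned channel %s", ch)
    if not kept:
        raise ValueError("all channels pruned")
    return kept


def intensity_to_od(raw: Signal) -> Signal:
    """ΔOD(t) = −log10(I(t) / mean I); zero-mean-ish by construction."""
    v = raw.values
    if np.any(v <= 0):
        raise ValueError(f"{raw.label}: nonpositive intensity sample")
    od = -np.log10(v / v.mean())
    return raw.copy_with(od, unit="OD")


def wavelet_motion_correct(od: Signal, iqr_mult: float = 1.5,
                           wavelet: str = "db3",
                           min_scale_s: float = 10.0) -> Signal:
    """Zero outlying wavelet detail coefficients and reconstruct.

    Decomposes to the level whose coarsest detail scale exceeds
    ``min_scale_s``; within each detail level, coefficients outside
    ``median ± iqr_mult·IQR``-style quartile fences are set to zero —
    spike-like transients concentrate there, while smooth physiology
    stays within the fences.
    """
    target = int(np.ceil(np.log2(od.fs * min_scale_s)))
    max_lvl = pywt.dwt_max_level(od.n, pywt.Wavelet(wavelet).dec_len)
    level = max(1, min(target, max_lvl))
    if max_lvl < 1:
        warnings.warn(f"{od.label}: too short for wavelet correction, passthrough")
        return od
    coeffs = pywt.wavedec(od.values, wavelet, level=level, mode="symmetric")
    for k in range(1, len(coeffs)):
        c = coeffs[k]
        q1, q3 = np.percentile(c, [25, 75])
        iqr = q3 - q1
        fence = (q1 - iqr_mult * iqr, q3 + iqr_mult * iqr)
        coeffs[k] = np.where((c < fence[0]) | (c > fence[1]), 0.0, c)
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric")[:od.n]
    return od.copy_with(rec)


def bandpass_od(od: Signal, band: tuple = (0.01, 0.5), order: int = 3) -> Signal:
    """Zero-phase band-pass of the optical-density series (default
    0.01–0.5 Hz, keeping the hemodynamic band and dropping drift and
    cardiac pulsation)."""
    nyq = od.fs / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = sps.butter(order, [band[0] / nyq, hi / nyq], btype="bandpass",
                     output="sos")
    return od.copy_with(sps.sosfiltfilt(sos, od.values))


def flag_motion(od: Signal, sd_thresh: float = 15.0, amp_thresh: float = 0.7,
                t_motion: float = 1.0, t_mask: float = 1.0) -> np.ndarray:
    """Boolean artifact mask: True where the excursion within any
    ``t_motion`` window exceeds ``sd_thresh``×SD or ``amp_thresh``
    absolute, extended by ``t_mask`` on each side."""
    w = max(2, int(round(t_motion * od.fs)))
    v = od.values
    sd = float(np.std(np.diff(v))) * np.sqrt(w)  # scale of w-sample change
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    excursion = maximum_filter1d(v, w) - minimum_filter1d(v, w)
    hit = (excursion > sd_thresh * sd) | (excursion > amp_thresh)
    if hit.any():
        ext = max(1, int(round(t_mask * od.fs)))
        hit = maximum_filter1d(hit.astype(np.uint8), 2 * ext + 1).astype(bool)
    return hit


def mbll(od_by_wl: dict, constants: OpticalConstants, distance_cm: float
         ) -> tuple[np.ndarray, np.ndarray]:
    """Solve the modified Beer–Lambert 2×2 system per sample.

    OD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR)·d·DPF(λ), with concentrations
    in mM; returns (ΔHbO, ΔHbR) in μM.
    """
    wavelengths = tuple(sorted(od_by_wl))
    E = constants.matrix(wavelengths)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    L = np.array([distance_cm * constants.dpf[wl] for wl in wavelengths])
    od = np.vstack([od_by_wl[wl].values for wl in wavelengths]) / L[:, None]
    conc_mM = np.linalg.solve(E, od)
    return conc_mM[0] * 1000.0, conc_mM[1] * 1000.0


def process_channels(raw: dict, montage: Montage,
                     constants: OpticalConstants | None = None,
                     band: tuple = (0.01, 0.5), iqr_mult: float = 1.5,
                     motion_kw: dict | None = None,
                     prune: bool = True) -> HbSeries:
    """Raw intensities → pruned, motion-corrected, filtered ΔHb series."""
    constants = constants or OpticalConstants()
    kept = prune_channels(raw) if prune else sorted({ch for ch, _ in raw})
    hbo, hbr, mask = {}, {}, {}
    for ch in kept:
        chan = next(c for c in montage.channels if c.name == ch)
        od_by_wl, hits = {}, []
        for wl in montage.wavelengths:
            od = intensity_to_od(raw[(ch, wl)])
            od = wavelet_motion_correct(od, iqr_mult=iqr_mult)
            od = bandpass_od(od, band=band)
            hits.append(flag_motion(od, **(motion_kw or {})))
            od_by_wl[wl] = od
        o, r = mbll(od_by_wl, constants, chan.distance_cm)
        hbo[ch], hbr[ch] = o, r
        mask[ch] = np.logical_or.reduce(hits)
    fs = next(iter(raw.values())).fs
    return HbSeries(hbo=hbo, hbr=hbr, fs=fs, mask=mask)


def _epoch_channel(values: np.ndarray, mask: np.ndarray, fs: float,
                   events: EventTable, window: tuple, reject_win: tuple
                   ) -> EpochSet:
    v = values.copy()
    sig = Signal(fs=fs, values=v, unit="uM")
    ep = epoch_baseline(sig, events, window=window, baseline=(window[0], 0.0))
    # reject epochs with any masked sample in the rejection window
    msig = Signal(fs=fs, values=mask.astype(float), unit="")
    mep = epoch_baseline(msig, events, window=window, baseline=(window[0], 0.0))
    rej = mep.data[:, mep._win_slice((max(window[0], reject_win[0]),
                                      min(window[1], reject_win[1])))]
    # baseline subtraction shifted the mask; recover by thresholding spread
    bad = (rej.max(axis=1) - rej.min(axis=1)) > 0.5
    ep.data[bad] = np.nan
    return ep


def block_average(hb: HbSeries, events: EventTable,
                  window: tuple = (-4.0, 30.0),
                  reject_window: tuple = (-5.0, 20.0)) -> dict:
    """Event-locked chromophore epochs per channel.

    Epochs containing any masked sample inside ``reject_window`` are
    dropped (set fully NaN) before any averaging; the remainder are
    referenced to the pre-stimulus mean.  Returns
    ``{channel: {"HbO": EpochSet, "HbR": EpochSet, "HbT": EpochSet}}``.
    """
    out = {}
    for ch in hb.channels():
        m = hb.mask[ch] if hb.mask else np.zeros_like(hb.hbo[ch], dtype=bool)
        out[ch] = {
            "HbO": _epoch_channel(hb.hbo[ch], m, hb.fs, events, window,
                                  reject_window),
            "HbR": _epoch_channel(hb.hbr[ch], m, hb.fs, events, window,
                                  reject_window),
        }
        e = out[ch]["HbO"]
        hbt = EpochSet(data=out[ch]["HbO"].data + out[ch]["HbR"].data,
                       fs=e.fs, window=e.window, baseline=e.baseline,
                       labels=e.labels, trials=e.trials, unit=e.unit)
        out[ch]["HbT"] = hbt
    return out


def roi_collapse(channel_epochs: dict, montage: Montage) -> dict:
    """Unweighted mean of channel epochs per ROI.

    Returns ``{roi: {chromophore: EpochSet}}``; an ROI whose channels were
    all pruned is reported missing with a log entry.
    """
    out = {}
    for roi in ROIS:
        names = [c.name for c in montage.roi_channels(roi)
                 if c.name in channel_epochs]
        if not names:
            logger.warning("ROI %s: no retained channels", roi)
            continue
        out[roi] = {}
        for chrom in ("HbO", "HbR", "HbT"):
            ref = channel_epochs[names[0]][chrom]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                data = np.nanmean(
                    np.stack([channel_epochs[n][chrom].data for n in names]),
                    axis=0)
            out[roi][chrom] = EpochSet(
                data=data, fs=ref.fs, window=ref.window, baseline=ref.baseline,
                labels=ref.labels, trials=ref.trials, unit=ref.unit)
    return out


def visual_regression(auditory: np.ndarray, visual: np.ndarray
                      ) -> np.ndarray:
    """Regress the visual-ROI time course out of one auditory channel.

    Least-squares fit ``auditory ≈ α + β·visual``; the residual keeps the
    channel-specific activity and drops the shared global component.  A
    zero-variance regressor returns the input unchanged with a warning.
    """
    v = np.asarray(visual, dtype=float)
    a = np.asarray(auditory, dtype=float)
    if a.shape != v.shape:
        raise ValueError("series must share length")
    if np.std(v) < 1e-15:
        warnings.warn("zero-variance visual regressor; returning input unchanged")
        return a.copy()
    vc = v - v.mean()
    beta = float(np.dot(a - a.mean(), vc) / np.dot(vc, vc))
    alpha = float(a.mean() - beta * v.mean())
    return a - (alpha + beta * v)


def regress_global(hb: HbSeries, montage: Montage) -> HbSeries:
    """Apply :func:`visual_regression` to every auditory channel, per
    chromophore, using the visual-ROI mean as the regressor."""
    vis = [c.name for c in montage.roi_channels("VSC") if c.name in hb.hbo]
    if not vis:
        warnings.warn("no visual channels retained; regression skipped")
        return hb
    vis_hbo = np.mean([hb.hbo[c] for c in vis], axis=0)
    vis_hbr = np.mean([hb.hbr[c] for c in vis], axis=0)
    hbo, hbr = {}, {}
    for ch in hb.channels():
        if montage.roi_map.get(ch) in ("LAC", "RAC"):
            hbo[ch] = visual_regression(hb.hbo[ch], vis_hbo)
            hbr[ch] = visual_regression(hb.hbr[ch], vis_hbr)
        else:
            hbo[ch], hbr[ch] = hb.hbo[ch].copy(), hb.hbr[ch].copy()
    return HbSeries(hbo=hbo, hbr=hbr, fs=hb.fs, mask=hb.mask)


def windowed_means(roi_epochs: dict,
                   tw1: tuple = (3.0, 12.0),
                   tw2: tuple = (13.0, 23.0)) -> pd.DataFrame:
    """Per (intensity, trial, ROI, chromophore, time-window) scalar means."""
    rows = []
    for roi, chroms in roi_epochs.items():
        for chrom, ep in chroms.items():
            for name, win in (("TW1", tw1), ("TW2", tw2)):
                tab = window_mean(ep, win)
                for _, r in tab.iterrows():
                    rows.append((roi, chrom, name, r["intensity"],
                                 int(r["trial"]), r["value"]))
    return pd.DataFrame(rows, columns=["roi", "chromophore", "tw",
                                       "intensity", "trial", "value"])
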