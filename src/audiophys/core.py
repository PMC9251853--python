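"""Shared time-series containers and epoching/band-power arithmetic.

Every stage of the pipeline works on three building blocks: a uniformly
sampled :class:`Signal`, a stimulus :class:`EventTable` (one row per tone
train), and the event-locked :class:`EpochSet` produced by
:func:`epoch_baseline`.  Band-integrated spectral summaries are returned as
:class:`BandPower`.

Windows are half-open ``[start, end)`` in seconds relative to the event
onset, and epochs are aligned to the sample nearest each onset — no
sub-sample interpolation, so the same events always produce the same rows.
Missing data propagate as NaN, never as zeros.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("audiophys")

#: Stimulus intensities used throughout (dBA).
INTENSITIES = (70.9, 77.9, 84.5, 89.5, 94.5)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Signal:
    """A uniformly sampled channel.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (> 0).
    values : ndarray
        Samples; at least two.
    t0 : float
        Time of the first sample in seconds.
    unit : str
        Physical unit label (e.g. ``"uS"``, ``"bpm"``, ``"a.u."``).
    label : str
        Channel name.
    """

    fs: float
    values: np.ndarray
    t0: float = 0.0
    unit: str = "a.u."
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a Signal needs at least 2 samples in one dimension")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, values: np.ndarray, **kw) -> "Signal":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    # -- I/O: CSV with JSON sidecar ------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"value": self.values}).to_csv(path, index=False)
        sidecar = {"fs": self.fs, "t0": self.t0, "unit": self.unit, "label": self.label}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Signal":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = pd.read_csv(path)["value"].to_numpy()
        return cls(fs=meta["fs"], values=values, t0=meta.get("t0", 0.0),
                   unit=meta.get("unit", "a.u."), label=meta.get("label", ""))


class EventTable:
    """Stimulus onsets with intensity labels and trial indices.

    Wraps a DataFrame with columns ``onset_s``, ``intensity_dBA``, ``trial``.
    Onsets must be strictly increasing and intensities drawn from a fixed
    label set with equal trial counts per intensity.
    """

    COLUMNS = ("onset_s", "intensity_dBA", "trial")

    def __init__(self, df: pd.DataFrame, intensities: Sequence[float] = INTENSITIES,
                 require_balanced: bool = True):
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        onsets = df["onset_s"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        labels = df["intensity_dBA"].to_numpy(dtype=float)
        allowed = np.asarray(intensities, dtype=float)
        if not np.all(np.isin(labels, allowed)):
            bad = sorted(set(labels) - set(allowed))
            raise ValueError(f"unknown intensity labels: {bad}")
        counts = df.groupby("intensity_dBA").size()
        if require_balanced and counts.nunique() > 1:
            raise ValueError(f"unbalanced trials per intensity: {counts.to_dict()}")
        self.df = df
        self.intensities = tuple(float(v) for v in allowed)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["intensity_dBA"].to_numpy(dtype=float)

    @property
    def trials(self) -> np.ndarray:
        return self.df["trial"].to_numpy(dtype=int)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"), **kw)


@dataclass
class EpochSet:
    """Event-locked epochs, one row per surviving event.

    ``data`` has shape (events, samples); the relative time of column ``j``
    is ``window[0] + j / fs``.  ``labels``/``trials`` carry the intensity and
    trial index of each row.  After :func:`epoch_baseline` the mean of each
    row over the baseline window is zero.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    baseline: tuple[float, float]
    labels: np.ndarray
    trials: np.ndarray
    unit: str = "a.u."

    @property
    def rel_times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.fs

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def _win_slice(self, win: tuple[float, float]) -> slice:
        lo = int(round((win[0] - self.window[0]) * self.fs))
        hi = int(round((win[1] - self.window[0]) * self.fs))
        return slice(lo, hi)


@dataclass
class BandPower:
    """Absolute and normalized band powers of one spectrum.

    ``vlf``/``lf``/``hf`` are trapezoid-integrated absolute powers
    (signal-unit²); ``lfnu``/``hfnu`` are percentages of LF+HF (NaN when
    LF+HF is zero), and ``lf_hf`` their ratio.
    """

    vlf: float
    lf: float
    hf: float
    lfnu: float
    hfnu: float
    lf_hf: float
    edges: dict = field(default_factory=dict)
    low_resolution: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def epoch_baseline(signal: Signal, events: EventTable,
                   window: tuple[float, float] = (-5.0, 50.0),
                   baseline: tuple[float, float] = (-5.0, 0.0)) -> EpochSet:
    """Extract baseline-subtracted event-locked epochs.

    Each event contributes the samples in ``[onset+window[0], onset+window[1])``
    minus the mean over ``[onset+baseline[0], onset+baseline[1])`` (the default
    geometry is a −5..50 s epoch referenced to a 5 s pre-stimulus baseline).
    Events whose window falls outside the recording are excluded with a
    warning; an empty result is an error.
    """
    if not (window[0] <= baseline[0] and baseline[1] <= window[1]):
        raise ValueError(f"baseline {baseline} must lie within window {window}")
    n_win = int(round((window[1] - window[0]) * signal.fs))
    b_lo = int(round((baseline[0] - window[0]) * signal.fs))
    b_hi = int(round((baseline[1] - window[0]) * signal.fs))
    rows, labels, trials = [], [], []
    for onset, lab, tr in zip(events.onsets, events.labels, events.trials):
        i_on = int(round((onset - signal.t0) * signal.fs))
        i0 = i_on + int(round(window[0] * signal.fs))
        if i0 < 0 or i0 + n_win > signal.n:
            warnings.warn(f"event at {onset:.1f}s: window outside recording, excluded")
            continue
        row = signal.values[i0:i0 + n_win].astype(float).copy()
        base = row[b_lo:b_hi]
        good = np.isfinite(base)
        if not good.any():
            warnings.warn(f"event at {onset:.1f}s: baseline fully missing, excluded")
            continue
        rows.append(row - base[good].mean())
        labels.append(lab)
        trials.append(tr)
    if not rows:
        raise ValueError("no events with a complete window inside the recording")
    return EpochSet(data=np.vstack(rows), fs=signal.fs, window=window,
                    baseline=baseline, labels=np.asarray(labels),
                    trials=np.asarray(trials, dtype=int), unit=signal.unit)


def window_mean(epochs: EpochSet, win: tuple[float, float]) -> pd.DataFrame:
    """Per-epoch mean over a relative-time window.

    Returns a DataFrame (intensity, trial, value); NaN samples (flagged /
    missing) are excluded from the mean, and a fully missing window yields
    NaN for that epoch.
    """
    if win[0] < epochs.window[0] - 1e-9 or win[1] > epochs.window[1] + 1e-9:
        raise ValueError(f"window {win} outside epoch window {epochs.window}")
    seg = epochs.data[:, epochs._win_slice(win)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        vals = np.nanmean(seg, axis=1)
    return pd.DataFrame({"intensity": epochs.labels, "trial": epochs.trials,
                         "value": vals})


def _band_integral(freqs: np.ndarray, power: np.ndarray,
                   lo: float, hi: float) -> float:
    """Trapezoid integral of a sampled PSD over [lo, hi], interpolating at
    the band edges so partial grid cells contribute exactly."""
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, power)
    return float(np.trapezoid(vals, grid))


def band_power(freqs: np.ndarray, power: np.ndarray,
               edges: dict | None = None,
               total: str = "lf_hf") -> BandPower:
    """Integrate a PSD into VLF/LF/HF bands with normalized units.

    ``edges`` maps band names to (lo, hi) Hz pairs; defaults to the HRV
    convention VLF 0–0.04, LF 0.04–0.15, HF 0.15–0.5 Hz.  Normalized units
    divide by LF+HF (``total="lf_hf"``) or by the whole integrated spectrum
    (``total="spectrum"``) and multiply by 100.  When the denominator is
    zero the normalized units and ratio are NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.ndim != 1 or freqs.shape != power.shape:
        raise ValueError("freqs and power must be matching 1-D arrays")
    if np.any(np.diff(freqs) <= 0) or freqs[0] < 0:
        raise ValueError("frequencies must be nonnegative and increasing")
    if np.any(power < -1e-12):
        raise ValueError("power must be nonnegative")
    edges = dict(edges or {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.5)})
    vlf = _band_integral(freqs, power, *edges.get("vlf", (0.0, 0.0)))
    lf = _band_integral(freqs, power, *edges["lf"])
    hf = _band_integral(freqs, power, *edges["hf"])
    if total == "lf_hf":
        denom = lf + hf
    elif total == "spectrum":
        denom = _band_integral(freqs, power, freqs[0], freqs[-1])
    else:
        raise ValueError(f"unknown normalization total {total!r}")
    if denom > 0:
        lfnu, hfnu = 100.0 * lf / denom, 100.0 * hf / denom
    else:
        lfnu = hfnu = np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return BandPower(vlf=vlf, lf=lf, hf=hf, lfnu=lfnu, hfnu=hfnu,
                     lf_hf=lf_hf, edges=edges)


def zscore_by_subject(table: pd.DataFrame, value: str = "value",
                      by: str | None = None) -> pd.DataFrame:
    """Return a copy with a z-scored value column (per group when ``by``)."""
    out = table.copy()

    def _z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    if by is None:
        out[value + "_z"] = _z(out[value])
    else:
        out[value + "_z"] = out.groupby(by)[value].transform(_z)
    return out
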