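"""Seeded synthetic sessions with known ground truth.

The generator emulates a graded-intensity auditory session: five tone-train
intensities (70.9–94.5 dBA), seven trials each, 20 tones of 1003 Hz / 70 ms
per train, 30 s of rest between trains.  It emits the four modalities the
analysis consumes —

* ECG: beat times from a mean-rate process with LF (~0.1 Hz) and HF
  (~0.25 Hz) modulation, a QRS-like template at each beat;
* PPG: one pulse per beat, delayed by a controllable transit time, with a
  controllable amplitude;
* EDA: slow tonic drift plus Bernoulli event-locked skin-conductance
  responses shaped by the Bateman kernel;
* fNIRS: per-channel hemodynamic responses plus a *shared global component*
  in every channel, pushed forward through the modified Beer–Lambert law to
  dual-wavelength optical intensities with cardiac/Mayer/respiratory
  oscillations and optional motion spikes.

Intensity-conditional effects (an HR dip, PPG amplitude and PTT decreases,
a global ΔHbO decrease — by default only at the highest intensity) are
injected through `EffectSpec`, and everything injected is recorded in
`GroundTruth` so downstream stages can be scored against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import INTENSITIES, EventTable, Signal
from .hemodynamics import Montage, OpticalConstants, default_montage

__all__ = [
    "EffectSpec", "SessionConfig", "GroundTruth", "Session",
    "make_schedule", "synth_tone", "synth_cardiac", "synth_eda",
    "synth_fnirs", "synth_session", "canonical_hrf",
]


@dataclass
class EffectSpec:
    """Intensity-conditional deviations injected after each tone-train onset.

    All deltas are relative to the session baseline; windows are (start, end)
    seconds post-onset with 0.5 s raised-cosine ramps.
    """

    dhr_bpm: float = 0.0            # HR change over hr_window
    hr_window: tuple = (0.0, 3.0)
    dppg_frac: float = 0.0          # fractional PPG amplitude change
    ppg_window: tuple = (2.0, 10.0)
    dptt_ms: float = 0.0            # transit-time change
    ptt_window: tuple = (4.0, 12.0)
    dhbo_um: float = 0.0            # global HbO change (all channels)
    dhbr_um: float = 0.0            # global HbR change
    scr_prob: float = 0.3           # P(event-locked SCR)
    scr_amp_us: float = 0.3         # SCR amplitude (uS)


def _default_effects() -> dict:
    """Null effects except the highest intensity: the response pattern the
    study conditions posit (HR dip, PPG/PTT/HbO decrease at 94.5 dBA)."""
    eff = {i: EffectSpec() for i in INTENSITIES}
    eff[94.5] = EffectSpec(dhr_bpm=-3.0, dppg_frac=-0.20, dptt_ms=-10.0,
                           dhbo_um=-0.2, dhbr_um=0.05)
    return eff


@dataclass
class SessionConfig:
    """Design and generator parameters for one synthetic session."""

    intensities: tuple = INTENSITIES
    trials_per_intensity: int = 7
    tones_per_trial: int = 20
    tone_duration_s: float = 0.070
    tone_freq_hz: float = 1003.0
    tone_ramp_s: float = 0.005
    inter_tone_interval_s: float = 0.430
    rest_s: float = 30.0
    lead_in_s: float = 40.0
    tail_s: float = 60.0
    seed: int = 0

    # modality sampling rates (Hz); desk-scale defaults, override for 2 kHz
    fs_cardiac: float = 250.0
    fs_eda: float = 20.0
    fs_fnirs: float = 4.8
    fs_audio: float = 44100.0

    # cardiac baseline; modulation frequencies deliberately incommensurate
    # with the 40 s trial grid so event-locked averages see varying phase
    hr_bpm: float = 70.0
    hr_lf_bpm: float = 2.0          # ~0.1 Hz rate modulation depth
    hr_lf_hz: float = 0.095
    hr_hf_bpm: float = 1.5          # ~0.25 Hz (respiratory) depth
    hr_hf_hz: float = 0.265
    hr_wander_bpm: float = 1.0      # slow random rate drift (SD)
    ptt_ms: float = 250.0
    ptt_jitter_ms: float = 3.0
    ppg_amp: float = 1.0
    ppg_amp_jitter: float = 0.03
    ecg_noise: float = 0.05
    ppg_noise: float = 0.02

    # electrodermal baseline
    eda_level_us: float = 8.0
    eda_drift_us: float = 0.4       # peak-to-peak slow drift
    eda_noise: float = 0.01
    scr_tau_rise: float = 0.75
    scr_tau_decay: float = 3.75
    spontaneous_scr_per_min: float = 0.5

    # fNIRS baseline
    hbo_local_um: float = 0.10      # auditory-channel response amplitude
    hbr_local_um: float = -0.03
    hbo_visual_um: float = 0.02     # weak local visual response
    hbr_visual_um: float = -0.006
    stim_block_s: float = 10.0      # local response boxcar
    global_block_s: float = 20.0    # intensity-effect boxcar (global)
    mayer_um: float = 0.3       # Mayer-wave depth in the global component
    wander_um: float = 0.1      # slow smooth global drift (SD)
    resp_od: float = 2e-3
    cardiac_od: float = 5e-3
    od_noise: float = 5e-4
    motion_spike_rate_per_min: float = 0.0
    motion_spike_od: float = 0.1

    effects: dict = field(default_factory=_default_effects)

    @property
    def trial_duration_s(self) -> float:
        return self.tones_per_trial * (self.tone_duration_s + self.inter_tone_interval_s)

    @property
    def n_trials(self) -> int:
        return self.trials_per_intensity * len(self.intensities)

    @property
    def duration_s(self) -> float:
        return (self.lead_in_s + self.n_trials * (self.trial_duration_s + self.rest_s)
                + self.tail_s)

    def validate(self) -> None:
        if self.trials_per_intensity <= 0 or self.tones_per_trial <= 0:
            raise ValueError("trial/tone counts must be positive")
        if self.fs_cardiac <= 2 * 35:
            raise ValueError("fs_cardiac must exceed twice the QRS bandwidth")
        if self.hr_bpm <= 0:
            raise ValueError("baseline HR must be positive")


@dataclass
class GroundTruth:
    """Everything injected, recorded by construction."""

    r_times: np.ndarray = None            # s
    ptt_ms: np.ndarray = None             # per beat
    ppg_amp: np.ndarray = None            # per beat
    scr_events: pd.DataFrame = None       # onset_s, amplitude_us, event_index
    tonic: np.ndarray = None              # uS on the EDA grid
    hb_true: dict = None                  # channel -> (hbo uM, hbr uM) arrays
    global_hbo: np.ndarray = None
    global_hbr: np.ndarray = None


@dataclass
class Session:
    """One complete synthetic recording plus its truth."""

    config: SessionConfig
    events: EventTable
    ecg: Signal
    ppg: Signal
    eda: Signal
    fnirs: dict                 # (channel, wavelength_nm) -> Signal
    montage: Montage
    truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth_gate(t: np.ndarray, start: float, end: float,
                 ramp: float = 0.5) -> np.ndarray:
    """Raised-cosine gated boxcar on [start, end] (unit plateau)."""
    g = np.zeros_like(t)
    rise = (t >= start) & (t < start + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / ramp))
    g[(t >= start + ramp) & (t <= end - ramp)] = 1.0
    fall = (t > end - ramp) & (t <= end)
    g[fall] = 0.5 * (1 - np.cos(np.pi * (end - t[fall]) / ramp))
    return g


def _event_profile(t: np.ndarray, onsets: np.ndarray, deltas: np.ndarray,
                   window: tuple, ramp: float = 0.5) -> np.ndarray:
    out = np.zeros_like(t)
    for onset, d in zip(onsets, deltas):
        if d == 0.0:
            continue
        lo, hi = onset + window[0], onset + window[1]
        sel = (t >= lo - ramp) & (t <= hi + ramp)
        out[sel] += d * _smooth_gate(t[sel], lo, hi, ramp)
    return out


def canonical_hrf(t: np.ndarray, peak: float = 5.4, under: float = 10.8,
                  ratio: float = 0.35) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, unit peak."""
    from scipy.stats import gamma as _gamma
    h = _gamma.pdf(t, a=6.0, scale=peak / 5.0) \
        - ratio * _gamma.pdf(t, a=12.0, scale=under / 11.0)
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_schedule(config: SessionConfig, rng: np.random.Generator | None = None
                  ) -> EventTable:
    """Randomized (seeded) trial order with equal counts per intensity.

    One event row per tone train; inter-onset gap = train duration + rest.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    labels = np.repeat(np.asarray(config.intensities, dtype=float),
                       config.trials_per_intensity)
    rng.shuffle(labels)
    onsets = config.lead_in_s + np.arange(config.n_trials) * (
        config.trial_duration_s + config.rest_s)
    trial_no = np.zeros(len(labels), dtype=int)
    seen: dict = {}
    for k, lab in enumerate(labels):
        seen[lab] = seen.get(lab, 0) + 1
        trial_no[k] = seen[lab]
    df = pd.DataFrame({"onset_s": onsets, "intensity_dBA": labels,
                       "trial": trial_no})
    return EventTable(df, intensities=config.intensities)


def synth_tone(config: SessionConfig) -> Signal:
    """One stimulus tone: a sinusoid with linear rise/fall ramps."""
    if config.tone_duration_s < 2 * config.tone_ramp_s:
        raise ValueError("tone duration must cover both ramps")
    n = int(round(config.tone_duration_s * config.fs_audio))
    t = np.arange(n) / config.fs_audio
    env = np.minimum(1.0, np.minimum(t / config.tone_ramp_s,
                                     (config.tone_duration_s - 1 / config.fs_audio - t)
                                     / config.tone_ramp_s))
    env = np.clip(env, 0.0, 1.0)
    return Signal(fs=config.fs_audio,
                  values=env * np.sin(2 * np.pi * config.tone_freq_hz * t),
                  unit="a.u.", label="tone")


def _beat_times(config: SessionConfig, events: EventTable,
                t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integrate the instantaneous rate and fire a beat at each unit phase."""
    from scipy.ndimage import gaussian_filter1d
    rate = np.full_like(t, config.hr_bpm)
    rate += config.hr_lf_bpm * np.sin(2 * np.pi * config.hr_lf_hz * t
                                      + rng.uniform(0, 2 * np.pi))
    rate += config.hr_hf_bpm * np.sin(2 * np.pi * config.hr_hf_hz * t
                                      + rng.uniform(0, 2 * np.pi))
    if config.hr_wander_bpm > 0:
        # smooth drift built on a coarse 1 Hz grid, then interpolated
        tc = np.arange(0.0, t[-1] + 2.0, 1.0)
        w = gaussian_filter1d(rng.normal(0, 1, tc.size), 30.0)
        w *= config.hr_wander_bpm * np.sqrt(2 * np.sqrt(np.pi) * 30.0)
        rate += np.interp(t, tc, w)
    for lab in set(events.labels):
        eff = config.effects[lab]
        sel = events.labels == lab
        rate += _event_profile(t, events.onsets[sel],
                               np.full(sel.sum(), eff.dhr_bpm), eff.hr_window)
    if np.any(rate <= 0):
        raise ValueError("instantaneous HR fell to zero or below")
    phase = np.cumsum(rate / 60.0) / config.fs_cardiac
    k = np.arange(1, int(phase[-1]))
    return np.interp(k, phase, t)


def synth_cardiac(config: SessionConfig, events: EventTable,
                  rng: np.random.Generator) -> tuple[Signal, Signal, GroundTruth]:
    """ECG + PPG pair with per-beat transit-time and amplitude truth.

    The QRS template peaks exactly at each beat time; each PPG pulse is
    placed so that its steepest upslope — the pulse-arrival fiducial — sits
    at ``beat + PTT``.
    """
    config.validate()
    n = int(round(config.duration_s * config.fs_cardiac))
    t = np.arange(n) / config.fs_cardiac
    r_times = _beat_times(config, events, t, rng)

    # per-beat truth
    ptt = np.full(r_times.size, config.ptt_ms)
    amp = np.full(r_times.size, config.ppg_amp)
    for lab in set(events.labels):
        eff = config.effects[lab]
        sel = events.labels == lab
        ptt += _event_profile(r_times, events.onsets[sel],
                              np.full(sel.sum(), eff.dptt_ms), eff.ptt_window)
        amp *= 1.0 + _event_profile(r_times, events.onsets[sel],
                                    np.full(sel.sum(), eff.dppg_frac),
                                    eff.ppg_window)
    ptt = ptt + rng.normal(0.0, config.ptt_jitter_ms, r_times.size)
    amp = amp * (1.0 + rng.normal(0.0, config.ppg_amp_jitter, r_times.size))

    # ECG: Mexican-hat QRS at each beat (sub-sample-accurate placement)
    ecg = np.zeros(n)
    sigma = 0.010
    half = int(round(5 * sigma * config.fs_cardiac))
    for tb in r_times:
        i = int(round(tb * config.fs_cardiac))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        tau = t[lo:hi] - tb
        ecg[lo:hi] += (1 - (tau / sigma) ** 2) * np.exp(-tau ** 2 / (2 * sigma ** 2))
    ecg += rng.normal(0.0, config.ecg_noise, n)

    # PPG: sin^2 pulse, steepest upslope (at T/4 from pulse onset) at tb+ptt
    ppg = np.zeros(n)
    T = 0.6
    n_pulse = int(round(T * config.fs_cardiac))
    for tb, p_ms, a in zip(r_times, ptt, amp):
        onset = tb + p_ms / 1000.0 - T / 4.0
        i0 = int(np.ceil(onset * config.fs_cardiac))
        lo, hi = max(0, i0), min(n, i0 + n_pulse)
        if lo >= hi:
            continue
        tau = t[lo:hi] - onset
        ppg[lo:hi] += a * np.sin(np.pi * tau / T) ** 2
    ppg += rng.normal(0.0, config.ppg_noise, n)

    truth = GroundTruth(r_times=r_times, ptt_ms=ptt, ppg_amp=amp)
    return (Signal(fs=config.fs_cardiac, values=ecg, unit="mV", label="ECG"),
            Signal(fs=config.fs_cardiac, values=ppg, unit="a.u.", label="PPG"),
            truth)


def synth_eda(config: SessionConfig, events: EventTable,
              rng: np.random.Generator) -> tuple[Signal, GroundTruth]:
    """Tonic drift plus Bernoulli event-locked SCRs on the Bateman kernel."""
    for lab in config.intensities:
        if config.effects[lab].scr_amp_us < 0:
            raise ValueError("SCR amplitude must be nonnegative")
    n = int(round(config.duration_s * config.fs_eda))
    t = np.arange(n) / config.fs_eda
    tonic = (config.eda_level_us
             + 0.5 * config.eda_drift_us * np.sin(2 * np.pi * t / 600.0 + 0.3)
             + 0.1 * config.eda_drift_us * (t / t[-1]))

    tr, td = config.scr_tau_rise, config.scr_tau_decay
    tpk = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-tpk / td) - np.exp(-tpk / tr)

    rows = []
    for k, (onset, lab) in enumerate(zip(events.onsets, events.labels)):
        eff = config.effects[lab]
        if rng.random() < eff.scr_prob and eff.scr_amp_us > 0:
            lat = rng.uniform(1.2, 3.0)
            a = eff.scr_amp_us * rng.uniform(0.8, 1.2)
            rows.append((onset + lat, a, k))
    n_spont = rng.poisson(config.spontaneous_scr_per_min * config.duration_s / 60.0)
    for ts in np.sort(rng.uniform(5.0, config.duration_s - 20.0, n_spont)):
        rows.append((float(ts), 0.15 * rng.uniform(0.8, 1.2), -1))
    scr = pd.DataFrame(rows, columns=["onset_s", "amplitude_us", "event_index"]) \
        if rows else pd.DataFrame(columns=["onset_s", "amplitude_us", "event_index"])

    phasic = np.zeros(n)
    for _, row in scr.iterrows():
        tau = t - row["onset_s"]
        sel = tau >= 0
        phasic[sel] += row["amplitude_us"] * (
            np.exp(-tau[sel] / td) - np.exp(-tau[sel] / tr)) / peak
    eda = tonic + phasic + rng.normal(0.0, config.eda_noise, n)
    truth = GroundTruth(scr_events=scr, tonic=tonic)
    return Signal(fs=config.fs_eda, values=eda, unit="uS", label="EDA"), truth


def synth_fnirs(config: SessionConfig, events: EventTable,
                rng: np.random.Generator, montage: Montage | None = None
                ) -> tuple[dict, Montage, GroundTruth]:
    """Dual-wavelength optical intensities from a forward hemodynamic model.

    Channel-local responses (auditory ROIs strong, visual weak) ride on a
    global component shared by all channels; the configured intensity
    effects enter through that global component, so the visual-channel
    regression downstream can be scored against construction.
    """
    montage = montage or default_montage()
    constants = OpticalConstants()
    n = int(round(config.duration_s * config.fs_fnirs))
    t = np.arange(n) / config.fs_fnirs
    dt = 1.0 / config.fs_fnirs

    hrf = canonical_hrf(np.arange(0, 32.0, dt))

    def _response(block_s: float, amps: np.ndarray) -> np.ndarray:
        drive = np.zeros(n)
        for onset, a in zip(events.onsets, amps):
            sel = (t >= onset) & (t < onset + block_s)
            drive[sel] += a
        r = np.convolve(drive, hrf)[:n] * dt
        # normalize so the plateau of a unit boxcar response is ~1
        return r / (hrf.sum() * dt)

    amps_hbo = np.array([config.effects[i].dhbo_um for i in events.labels])
    amps_hbr = np.array([config.effects[i].dhbr_um for i in events.labels])
    g_hbo = (_response(config.global_block_s, amps_hbo)
             + config.mayer_um * np.sin(2 * np.pi * 0.1 * t + 0.7))
    g_hbr = (_response(config.global_block_s, amps_hbr)
             + 0.3 * config.mayer_um * np.sin(2 * np.pi * 0.1 * t + 2.0))
    # slow smooth global wander
    from scipy.ndimage import gaussian_filter1d
    g_hbo = g_hbo + gaussian_filter1d(rng.normal(0, 1, n), 50) * config.wander_um
    g_hbr = g_hbr + gaussian_filter1d(rng.normal(0, 1, n), 50) * 0.3 * config.wander_um

    ones = np.ones(len(events))
    local_aud_hbo = _response(config.stim_block_s, config.hbo_local_um * ones)
    local_aud_hbr = _response(config.stim_block_s, config.hbr_local_um * ones)
    local_vis_hbo = _response(config.stim_block_s, config.hbo_visual_um * ones)
    local_vis_hbr = _response(config.stim_block_s, config.hbr_visual_um * ones)

    signals: dict = {}
    hb_true: dict = {}
    for ch in montage.channels:
        roi = montage.roi_map[ch.name]
        if roi in ("LAC", "RAC"):
            hbo = local_aud_hbo + g_hbo
            hbr = local_aud_hbr + g_hbr
        else:
            hbo = local_vis_hbo + g_hbo
            hbr = local_vis_hbr + g_hbr
        hb_true[ch.name] = (hbo, hbr)
        for wl in montage.wavelengths:
            eps_o = constants.extinction[(wl, "HbO")]
            eps_r = constants.extinction[(wl, "HbR")]
            od = ((eps_o * hbo + eps_r * hbr) / 1000.0
                  * ch.distance_cm * constants.dpf[wl])
            od = od + config.cardiac_od * np.sin(2 * np.pi * 1.02 * t
                                                 + rng.uniform(0, 2 * np.pi))
            od = od + config.resp_od * np.sin(2 * np.pi * 0.3 * t
                                              + rng.uniform(0, 2 * np.pi))
            od = od + rng.normal(0.0, config.od_noise, n)
            n_spk = rng.poisson(config.motion_spike_rate_per_min
                                * config.duration_s / 60.0)
            for ts in rng.uniform(10.0, config.duration_s - 10.0, n_spk):
                tau = t - ts
                sel = tau >= 0
                od[sel] += config.motion_spike_od * np.exp(-tau[sel] / 0.5)
            i0 = rng.uniform(0.5, 1.5)
            signals[(ch.name, wl)] = Signal(
                fs=config.fs_fnirs, values=i0 * 10.0 ** (-od),
                unit="V", label=f"{ch.name}@{wl}nm")
    truth = GroundTruth(hb_true=hb_true, global_hbo=g_hbo, global_hbr=g_hbr)
    return signals, montage, truth


def synth_session(config: SessionConfig | None = None,
                  seed: int | None = None) -> Session:
    """Generate one complete seeded session (all modalities + truth)."""
    config = config or SessionConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = make_schedule(config, rng)
    ecg, ppg, tru_card = synth_cardiac(config, events, rng)
    eda, tru_eda = synth_eda(config, events, rng)
    fnirs, montage, tru_nirs = synth_fnirs(config, events, rng)
    truth = GroundTruth(
        r_times=tru_card.r_times, ptt_ms=tru_card.ptt_ms,
        ppg_amp=tru_card.ppg_amp, scr_events=tru_eda.scr_events,
        tonic=tru_eda.tonic, hb_true=tru_nirs.hb_true,
        global_hbo=tru_nirs.global_hbo, global_hbr=tru_nirs.global_hbr)
    return Session(config=config, events=events, ecg=ecg, ppg=ppg, eda=eda,
                   fnirs=fnirs, montage=montage, truth=truth)
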