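"""End-to-end orchestration: session in, statistical report out.

``run`` sequences the full analysis the way the study design prescribes:
cardiac (HR epochs in three windows, HRV time/frequency over the 50 s
post-stimulus span), vascular (rectified PPG amplitude, Lomb spectral
bands of the raw pulse, beat-wise PTT in two windows), electrodermal
(event-related SCL and the phasic decomposition metrics), hemodynamics
(the fNIRS chain, with and without visual-channel regression), and the
permutation inference on every metric table.  All randomness flows from
one seed; rerunning a config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import zlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac, electrodermal, hemodynamics, inference, vascular
from .core import EventTable, Signal, window_mean
from .synth import Session, SessionConfig, synth_session

logger = logging.getLogger("audiophys")

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the study's values."""

    seed: int = 0
    n_perm: int = 999
    synth: dict = field(default_factory=dict)   # SessionConfig overrides

    hr_fs_out: float = 4.0
    hr_windows: tuple = ((1.0, 3.0), (3.5, 5.5), (6.0, 8.0))
    ppg_metric_window: tuple = (4.0, 8.0)
    scl_metric_window: tuple = (2.0, 8.0)
    ptt_windows: tuple = ((6.0, 8.0), (8.0, 10.0))
    hrv_window_s: float = 50.0
    lomb_window_s: float = 12.0
    fnirs_tw1: tuple = (3.0, 12.0)
    fnirs_tw2: tuple = (13.0, 23.0)
    epoch_window: tuple = (-5.0, 50.0)
    baseline_window: tuple = (-5.0, 0.0)
    fnirs_epoch_window: tuple = (-4.0, 30.0)
    posthoc_alpha: float = 0.05
    out_dir: str | None = None


@dataclass
class Report:
    """Omnibus and post hoc tables plus per-stage QC counts."""

    stats: pd.DataFrame            # measure, metric, factor, F, p, eta2
    posthoc: pd.DataFrame          # measure, metric, level_a, level_b, p, p_fdr
    metrics: pd.DataFrame          # long per-trial metric values
    baseline_tests: pd.DataFrame
    qc: dict
    config: RunConfig


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Fill defaults, reject unknown keys, check window containment."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**raw)
    synth_known = {f.name for f in fields(SessionConfig)}
    bad = set(cfg.synth) - synth_known
    if bad:
        raise ValueError(f"unknown synth keys: {sorted(bad)}")
    for name in ("hr_windows", "ptt_windows"):
        for w in getattr(cfg, name):
            if w[0] >= w[1]:
                raise ValueError(f"{name}: inverted window {w}")
            if not (cfg.epoch_window[0] <= w[0] and w[1] <= cfg.epoch_window[1]):
                raise ValueError(f"{name}: window {w} outside epoch")
    for name in ("ppg_metric_window", "scl_metric_window",
                 "fnirs_tw1", "fnirs_tw2"):
        w = getattr(cfg, name)
        if w[0] >= w[1]:
            raise ValueError(f"{name}: inverted window {w}")
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be positive")
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _cardiac_stage(session: Session, cfg: RunConfig) -> dict:
    ecg_f = cardiac.filter_ecg(session.ecg)
    beats = cardiac.detect_r_peaks(ecg_f)
    hr = cardiac.hr_series(beats, cfg.hr_fs_out)
    from .core import epoch_baseline
    hr_ep = epoch_baseline(hr, session.events, window=cfg.epoch_window,
                           baseline=cfg.baseline_window)
    hr_rows = []
    for k, win in enumerate(cfg.hr_windows, start=1):
        tab = window_mean(hr_ep, win)
        tab["tw"] = f"TW{k}"
        hr_rows.append(tab)
    hr_tab = pd.concat(hr_rows, ignore_index=True)

    hrv_rows = []
    for onset, lab, tr in zip(session.events.onsets, session.events.labels,
                              session.events.trials):
        win = (onset, onset + cfg.hrv_window_s)
        try:
            td = cardiac.hrv_time(beats, window=win)
            bp = cardiac.hrv_spectrum(beats, window=win)
            hrv_rows.append((lab, tr, td.rmssd, td.sdnn, bp.lf, bp.hf,
                             bp.lfnu, bp.hfnu, bp.lf_hf))
        except ValueError:
            hrv_rows.append((lab, tr) + (np.nan,) * 7)
    hrv_tab = pd.DataFrame(hrv_rows, columns=[
        "intensity", "trial", "RMSSD", "SDNN", "aLF", "aHF",
        "LFnu", "HFnu", "LF_HF"])
    n_flagged = int(beats.flags.sum())
    return {"beats": beats, "hr_table": hr_tab, "hrv_table": hrv_tab,
            "qc": {"n_beats": beats.n, "n_flagged_beats": n_flagged}}


def _vascular_stage(session: Session, beats, cfg: RunConfig) -> dict:
    ppg_f = vascular.filter_ppg(session.ppg)
    ep = vascular.absolute_ppg_epochs(ppg_f, session.events,
                                      window=cfg.epoch_window,
                                      baseline=cfg.baseline_window)
    ppg_tab = window_mean(ep, cfg.ppg_metric_window)
    lomb_tab = vascular.ppg_lomb_bands(session.ppg, session.events,
                                       window_s=cfg.lomb_window_s)
    ptt = vascular.compute_ptt(beats, ppg_f)
    _, ptt_tab = vascular.ptt_epochs(ptt, session.events,
                                     window=cfg.epoch_window,
                                     baseline=cfg.baseline_window,
                                     windows=cfg.ptt_windows)
    return {"ppg_table": ppg_tab, "lomb_table": lomb_tab, "ptt_table": ptt_tab,
            "qc": {"n_ptt_flagged": int(ptt.flags.sum()),
                   "n_ptt": int(ptt.flags.size)}}


def _eda_stage(session: Session, cfg: RunConfig) -> dict:
    _, scl_tab = electrodermal.scl_epochs(session.eda, session.events,
                                          window=cfg.epoch_window,
                                          baseline=cfg.baseline_window,
                                          metric_window=cfg.scl_metric_window)
    cda = electrodermal.cda_decompose(session.eda)
    scr_tab = electrodermal.scr_metrics(cda, session.events)
    return {"scl_table": scl_tab, "scr_table": scr_tab,
            "qc": {"n_scrs": int(len(cda.scrs)), "cda_flagged": cda.flagged,
                   "tau": (cda.params.tau_rise, cda.params.tau_decay)}}


def _fnirs_stage(session: Session, cfg: RunConfig) -> dict:
    hb = hemodynamics.process_channels(session.fnirs, session.montage)
    out = {}
    for tag, series in (("raw", hb),
                        ("regressed", hemodynamics.regress_global(
                            hb, session.montage))):
        ep = hemodynamics.block_average(series, session.events,
                                        window=cfg.fnirs_epoch_window)
        roi = hemodynamics.roi_collapse(ep, session.montage)
        if tag == "regressed":
            roi = {k: v for k, v in roi.items() if k != "VSC"}
        out[tag] = hemodynamics.windowed_means(roi, tw1=cfg.fnirs_tw1,
                                               tw2=cfg.fnirs_tw2)
        out[tag + "_epochs"] = roi
    out["qc"] = {"n_channels": len(hb.channels()),
                 "mask_fraction": float(np.mean(
                     [m.mean() for m in hb.mask.values()])) if hb.mask else 0.0}
    return out


# ---------------------------------------------------------------------------
# inference assembly
# ---------------------------------------------------------------------------

def _oneway(tab: pd.DataFrame, measure: str, metric: str, value: str,
            cfg: RunConfig, seed_off: int, stats_rows, posthoc_rows,
            metrics_rows) -> None:
    sub = tab[["intensity", "trial", value]].rename(columns={value: "value"})
    for _, r in sub.iterrows():
        metrics_rows.append((measure, metric, r["intensity"], int(r["trial"]),
                             "", r["value"]))
    try:
        res = inference.permanova_oneway(sub["value"], sub["intensity"],
                                         n_perm=cfg.n_perm,
                                         seed=cfg.seed + seed_off)
    except ValueError as exc:
        logger.warning("%s/%s: PERMANOVA skipped (%s)", measure, metric, exc)
        stats_rows.append((measure, metric, "intensity", np.nan, np.nan, np.nan))
        return
    row = res.factors.iloc[0]
    stats_rows.append((measure, metric, "intensity", row["F"], row["p"],
                       row["eta2"]))
    ph = inference.pairwise_contrasts(sub, subject="trial")
    ph.insert(0, "metric", metric)
    ph.insert(0, "measure", measure)
    ph["omnibus_p"] = row["p"]
    posthoc_rows.append(ph)


def _twoway(tab: pd.DataFrame, measure: str, metric: str, cfg: RunConfig,
            seed_off: int, stats_rows, posthoc_rows, metrics_rows,
            factor_b: str = "tw") -> None:
    for _, r in tab.iterrows():
        metrics_rows.append((measure, metric, r["intensity"], int(r["trial"]),
                             r[factor_b], r["value"]))
    try:
        res = inference.permanova_twoway(tab["value"], tab["intensity"],
                                         tab[factor_b], n_perm=cfg.n_perm,
                                         seed=cfg.seed + seed_off,
                                         names=("intensity", factor_b))
    except ValueError as exc:
        logger.warning("%s/%s: PERMANOVA skipped (%s)", measure, metric, exc)
        for fac in ("intensity", factor_b, "interaction"):
            stats_rows.append((measure, metric, fac, np.nan, np.nan, np.nan))
        return
    for _, row in res.factors.iterrows():
        stats_rows.append((measure, metric, row["factor"], row["F"], row["p"],
                           row["eta2"]))
    p_int = res.p("intensity")
    sub = tab.groupby(["intensity", "trial"], as_index=False)["value"].mean()
    ph = inference.pairwise_contrasts(sub, subject="trial")
    ph.insert(0, "metric", metric)
    ph.insert(0, "measure", measure)
    ph["omnibus_p"] = p_int
    posthoc_rows.append(ph)


def run(config: RunConfig | dict, session: Session | None = None) -> Report:
    """Execute the full pipeline on a provided or freshly synthesized
    session and return the assembled report (optionally written to
    ``config.out_dir``)."""
    cfg = validate_config(config)
    if session is None:
        try:
            sc = SessionConfig(**cfg.synth)
            session = synth_session(sc, seed=cfg.seed)
        except Exception as exc:
            raise StageError("synthesis", exc) from exc

    stages = {}
    for name, fn in (("cardiac", lambda: _cardiac_stage(session, cfg)),):
        try:
            stages[name] = fn()
        except Exception as exc:     # noqa: BLE001 - stage boundary
            raise StageError(name, exc) from exc
    try:
        stages["vascular"] = _vascular_stage(session, stages["cardiac"]["beats"],
                                             cfg)
    except Exception as exc:
        raise StageError("vascular", exc) from exc
    try:
        stages["eda"] = _eda_stage(session, cfg)
    except Exception as exc:
        raise StageError("electrodermal", exc) from exc
    try:
        stages["fnirs"] = _fnirs_stage(session, cfg)
    except Exception as exc:
        raise StageError("hemodynamics", exc) from exc

    stats_rows, posthoc_rows, metrics_rows = [], [], []
    _twoway(stages["cardiac"]["hr_table"], "HR", "mean_HR", cfg, 11,
            stats_rows, posthoc_rows, metrics_rows)
    for met in ("RMSSD", "SDNN", "aLF", "aHF", "LFnu", "HFnu", "LF_HF"):
        _oneway(stages["cardiac"]["hrv_table"], "HRV", met, met, cfg,
                20 + zlib.crc32(met.encode()) % 100, stats_rows, posthoc_rows, metrics_rows)
    _oneway(stages["vascular"]["ppg_table"], "PPG", "mean_abs_PPG", "value",
            cfg, 31, stats_rows, posthoc_rows, metrics_rows)
    for met in ("lfnu", "hfnu", "lf_hf"):
        _oneway(stages["vascular"]["lomb_table"], "PSD_PPG", met.upper(), met,
                cfg, 40 + zlib.crc32(met.encode()) % 100, stats_rows, posthoc_rows, metrics_rows)
    _twoway(stages["vascular"]["ptt_table"], "PTT", "mean_PTT", cfg, 51,
            stats_rows, posthoc_rows, metrics_rows)
    _oneway(stages["eda"]["scl_table"], "SCL", "mean_EDA", "value", cfg, 61,
            stats_rows, posthoc_rows, metrics_rows)
    for met in ("AmpSum", "nSCR", "SCR", "PhasicMax", "tonic_mean"):
        _oneway(stages["eda"]["scr_table"], "SCR", met, met, cfg,
                70 + zlib.crc32(met.encode()) % 100, stats_rows, posthoc_rows, metrics_rows)

    baseline_rows = []
    for tag in ("raw", "regressed"):
        wm = stages["fnirs"][tag]
        for chrom in ("HbO", "HbR", "HbT"):
            for tw in ("TW1", "TW2"):
                sub = wm[(wm["chromophore"] == chrom) & (wm["tw"] == tw)]
                _twoway(sub, f"fNIRS_{tag}", f"{chrom}_{tw}", cfg,
                        1000 + zlib.crc32((tag + chrom + tw).encode()) % 500,
                        stats_rows, posthoc_rows, metrics_rows, factor_b="roi")
        if tag == "regressed":
            for chrom in ("HbO", "HbR", "HbT"):
                sub = wm[(wm["chromophore"] == chrom) & (wm["tw"] == "TW2")]
                coll = sub.groupby(["intensity", "trial"],
                                   as_index=False)["value"].mean()
                bt = inference.t_vs_baseline(coll)
                bt.insert(0, "metric", f"{chrom}_TW2")
                baseline_rows.append(bt)

    stats = pd.DataFrame(stats_rows, columns=["measure", "metric", "factor",
                                              "F", "p", "eta2"])
    posthoc = (pd.concat(posthoc_rows, ignore_index=True)
               if posthoc_rows else pd.DataFrame())
    metrics = pd.DataFrame(metrics_rows, columns=["measure", "metric",
                                                  "intensity", "trial", "tw",
                                                  "value"])
    baseline = (pd.concat(baseline_rows, ignore_index=True)
                if baseline_rows else pd.DataFrame())
    qc = {name: stages[name].get("qc", {}) for name in stages}
    report = Report(stats=stats, posthoc=posthoc, metrics=metrics,
                    baseline_tests=baseline, qc=qc, config=cfg)
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


def write_report(report: Report, out_dir: str | Path) -> None:
    """CSV tables plus a provenance manifest (config hash, seed, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.stats.to_csv(out / "stats.csv", index=False)
    report.posthoc.to_csv(out / "posthoc.csv", index=False)
    report.metrics.to_csv(out / "metrics.csv", index=False)
    report.baseline_tests.to_csv(out / "baseline_tests.csv", index=False)
    cfg_json = json.dumps(asdict(report.config), sort_keys=True, default=str)
    manifest = {"config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": report.config.seed, "version": __version__,
                "qc": _jsonable(report.qc)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.json").write_text(cfg_json)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# session serialization (the standard layout the pipeline consumes)
# ---------------------------------------------------------------------------

def save_session(session: Session, out_dir: str | Path) -> None:
    """Signals as CSV (+ JSON sidecars), events as TSV, montage as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.events.to_tsv(out / "events.tsv")
    session.ecg.to_csv(out / "ecg.csv")
    session.ppg.to_csv(out / "ppg.csv")
    session.eda.to_csv(out / "eda.csv")
    nirs = out / "fnirs"
    nirs.mkdir(exist_ok=True)
    for (ch, wl), sig in session.fnirs.items():
        sig.to_csv(nirs / f"{ch}_{wl}.csv")
    montage = {"wavelengths": list(session.montage.wavelengths),
               "channels": [{"source": c.source, "detector": c.detector,
                             "distance_cm": c.distance_cm,
                             "roi": session.montage.roi_map[c.name]}
                            for c in session.montage.channels]}
    (out / "montage.json").write_text(json.dumps(montage, indent=2))


def load_session(in_dir: str | Path) -> Session:
    """Inverse of :func:`save_session` (ground truth is not persisted)."""
    from .hemodynamics import Channel, Montage
    src = Path(in_dir)
    events = EventTable.from_tsv(src / "events.tsv")
    mj = json.loads((src / "montage.json").read_text())
    chans = [Channel(c["source"], c["detector"], c["distance_cm"])
             for c in mj["channels"]]
    roi = {Channel(c["source"], c["detector"]).name: c["roi"]
           for c in mj["channels"]}
    montage = Montage(channels=chans, wavelengths=tuple(mj["wavelengths"]),
                      roi_map=roi)
    fnirs = {}
    for (ch, wl) in [(c.name, wl) for c in chans for wl in montage.wavelengths]:
        fnirs[(ch, wl)] = Signal.from_csv(src / "fnirs" / f"{ch}_{wl}.csv")
    return Session(config=SessionConfig(), events=events,
                   ecg=Signal.from_csv(src / "ecg.csv"),
                   ppg=Signal.from_csv(src / "ppg.csv"),
                   eda=Signal.from_csv(src / "eda.csv"),
                   fnirs=fnirs, montage=montage, truth=None)
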