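"""Epoching, window means, and band-power arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from audiophys import (EventTable, Signal, band_power, epoch_baseline,
                       window_mean)
from audiophys.core import EpochSet


def _events(onsets, intensities=(70.9, 94.5)):
    labs = [intensities[i % len(intensities)] for i in range(len(onsets))]
    return EventTable(pd.DataFrame({"onset_s": onsets, "intensity_dBA": labs,
                                    "trial": range(1, len(onsets) + 1)}),
                      intensities=intensities, require_balanced=False)


class TestEpochBaseline:
    def test_constant_signal_gives_zero_epochs(self):
        sig = Signal(fs=10.0, values=np.full(2000, 3.7))
        ep = epoch_baseline(sig, _events([20.0, 60.0]), window=(-5, 50),
                            baseline=(-5, 0))
        assert np.allclose(ep.data, 0.0, atol=1e-12)
        assert ep.data.shape == (2, 550)

    def test_ramp_signal_closed_form(self):
        # value(t)=t, baseline (-5,0) mean over samples = t_event - 2.55
        # (half-open [-5,0) sample grid at 10 Hz: offsets -5.0..-0.1)
        fs = 10.0
        sig = Signal(fs=fs, values=np.arange(0, 1000) / fs)
        ep = epoch_baseline(sig, _events([10.0]), window=(-5, 50),
                            baseline=(-5, 0))
        tau = ep.rel_times
        base_mean = np.mean(np.arange(-50, 0) / fs)   # -2.55
        assert np.allclose(ep.data[0], tau - base_mean, atol=1e-9)

    def test_default_geometry_matches_config(self):
        sig = Signal(fs=20.0, values=np.random.default_rng(0).normal(size=4000))
        ep = epoch_baseline(sig, _events([30.0]))
        assert ep.window == (-5.0, 50.0)
        assert ep.baseline == (-5.0, 0.0)
        assert ep.data.shape[1] == int(55 * 20)
        b = ep.data[:, :int(5 * 20)]
        assert abs(b.mean()) < 1e-9

    def test_baseline_mean_zero_invariant(self):
        rng = np.random.default_rng(3)
        sig = Signal(fs=10.0, values=rng.normal(size=3000))
        ep = epoch_baseline(sig, _events([50.0, 100.0, 150.0]))
        lo = ep._win_slice((-5.0, 0.0))
        assert np.allclose(ep.data[:, lo].mean(axis=1), 0.0, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        sig = Signal(fs=10.0, values=rng.normal(size=2000))
        ep1 = epoch_baseline(sig, _events([30.0, 90.0]))
        # re-subtracting each epoch's baseline mean changes nothing
        lo = ep1._win_slice((-5.0, 0.0))
        again = ep1.data - ep1.data[:, lo].mean(axis=1, keepdims=True)
        assert np.allclose(again, ep1.data, atol=1e-12)

    def test_event_outside_recording_excluded_with_warning(self):
        sig = Signal(fs=10.0, values=np.zeros(700))
        with pytest.warns(UserWarning, match="outside recording"):
            ep = epoch_baseline(sig, _events([10.0, 65.0]))
        assert ep.n_epochs == 1

    def test_all_events_outside_raises(self):
        sig = Signal(fs=10.0, values=np.zeros(100))
        with pytest.raises(ValueError, match="no events"):
            epoch_baseline(sig, _events([500.0]))

    def test_labels_carried_over(self):
        sig = Signal(fs=10.0, values=np.zeros(3000))
        ep = epoch_baseline(sig, _events([20.0, 60.0, 100.0, 140.0]))
        assert list(ep.labels) == [70.9, 94.5, 70.9, 94.5]


class TestWindowMean:
    def _epochs(self, data, fs=10.0):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        return EpochSet(data=data, fs=fs, window=(-5.0, 50.0),
                        baseline=(-5.0, 0.0),
                        labels=np.full(data.shape[0], 70.9),
                        trials=np.arange(1, data.shape[0] + 1))

    def test_constant_epoch(self):
        ep = self._epochs(np.ones(550))
        assert window_mean(ep, (4, 8))["value"].iloc[0] == pytest.approx(1.0)

    def test_linear_epoch_midpoint(self):
        fs = 10.0
        tau = -5.0 + np.arange(550) / fs
        tab = window_mean(self._epochs(tau), (4, 8))
        # half-open [4, 8): samples 4.0..7.9, mean 5.95
        assert tab["value"].iloc[0] == pytest.approx(np.mean(tau[(tau >= 4) & (tau < 8)]))

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        base = rng.normal(size=550)
        m0 = window_mean(self._epochs(base), (4, 8))["value"].iloc[0]
        m1 = window_mean(self._epochs(a * base + b), (4, 8))["value"].iloc[0]
        assert m1 == pytest.approx(a * m0 + b, rel=1e-9, abs=1e-9)

    def test_missing_samples_excluded(self):
        row = np.ones(550)
        row[95:100] = np.nan   # inside (4,8) at 10 Hz
        tab = window_mean(self._epochs(row), (4, 8))
        assert tab["value"].iloc[0] == pytest.approx(1.0)

    def test_fully_missing_window_is_nan(self):
        row = np.ones(550)
        row[90:130] = np.nan
        tab = window_mean(self._epochs(row), (4, 8))
        assert np.isnan(tab["value"].iloc[0])

    def test_window_outside_epoch_raises(self):
        with pytest.raises(ValueError):
            window_mean(self._epochs(np.ones(550)), (49, 55))


class TestBandPower:
    def test_flat_psd_analytic(self):
        freqs = np.linspace(0.0, 0.5, 501)
        bp = band_power(freqs, np.ones_like(freqs),
                        edges={"vlf": (0, 0.04), "lf": (0.04, 0.15),
                               "hf": (0.15, 0.4)})
        assert bp.lf == pytest.approx(0.11, abs=1e-9)
        assert bp.hf == pytest.approx(0.25, abs=1e-9)
        assert bp.lfnu == pytest.approx(100 * 0.11 / 0.36, abs=1e-6)

    def test_single_line_at_lf(self):
        freqs = np.linspace(0, 0.5, 1001)
        psd = np.zeros_like(freqs)
        psd[np.argmin(np.abs(freqs - 0.1))] = 50.0
        bp = band_power(freqs, psd)
        assert bp.lfnu == pytest.approx(100.0)
        assert bp.hfnu == pytest.approx(0.0)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.linspace(0, 0.5, 101)
        psd = rng.uniform(0.1, 2.0, freqs.size)
        bp = band_power(freqs, psd)
        assert bp.lfnu + bp.hfnu == pytest.approx(100.0, abs=1e-6)

    def test_zero_lf_hf_gives_missing_nu(self):
        freqs = np.linspace(0, 0.5, 101)
        psd = np.where(freqs < 0.03, 1.0, 0.0)
        bp = band_power(freqs, psd)
        assert np.isnan(bp.lfnu) and np.isnan(bp.hfnu) and np.isnan(bp.lf_hf)

    def test_additive_over_disjoint_bands_and_grid_refinement(self):
        rng = np.random.default_rng(5)
        freqs = np.linspace(0, 0.5, 201)
        psd = rng.uniform(0.5, 1.5, freqs.size)
        bp = band_power(freqs, psd)
        total = np.trapezoid(psd, freqs)
        vlf_lf_hf = bp.vlf + bp.lf + bp.hf
        rest = total - np.interp(0.4, freqs, psd) * 0  # bands end at 0.5
        assert vlf_lf_hf == pytest.approx(total, rel=1e-9)
        # 2x finer grid changes band integrals < 1%
        f2 = np.linspace(0, 0.5, 401)
        bp2 = band_power(f2, np.interp(f2, freqs, psd))
        assert bp2.lf == pytest.approx(bp.lf, rel=0.01)
        assert bp2.hf == pytest.approx(bp.hf, rel=0.01)

    def test_total_spectrum_switch(self):
        freqs = np.linspace(0.0, 0.5, 501)
        bp = band_power(freqs, np.ones_like(freqs), total="spectrum")
        assert bp.lfnu == pytest.approx(100 * 0.11 / 0.5, abs=1e-6)


class TestEventTable:
    def test_rejects_nonincreasing_onsets(self):
        with pytest.raises(ValueError, match="increasing"):
            _events([10.0, 10.0])

    def test_rejects_unknown_intensity(self):
        df = pd.DataFrame({"onset_s": [1.0], "intensity_dBA": [50.0],
                           "trial": [1]})
        with pytest.raises(ValueError, match="unknown intensity"):
            EventTable(df)

    def test_rejects_unbalanced(self):
        df = pd.DataFrame({"onset_s": [1.0, 2.0, 3.0],
                           "intensity_dBA": [70.9, 70.9, 94.5],
                           "trial": [1, 2, 1]})
        with pytest.raises(ValueError, match="unbalanced"):
            EventTable(df, intensities=(70.9, 94.5))

    def test_tsv_roundtrip(self, tmp_path):
        ev = _events([10.0, 50.0])
        ev.to_tsv(tmp_path / "ev.tsv")
        back = EventTable.from_tsv(tmp_path / "ev.tsv",
                                   intensities=(70.9, 94.5),
                                   require_balanced=False)
        pd.testing.assert_frame_equal(ev.df, back.df)
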