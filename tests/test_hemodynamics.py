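"""fNIRS chain: pruning, OD, wavelet correction, mBLL, ROI, regression."""

import numpy as np
import pandas as pd
import pytest

from audiophys import (EventTable, OpticalConstants, Signal, bandpass_od,
                       flag_motion, intensity_to_od, mbll, prune_channels,
                       visual_regression, wavelet_motion_correct)
from audiophys.hemodynamics import (Channel, Montage, HbSeries, block_average,
                                    roi_collapse, windowed_means)

FS = 4.8


def _sig(values, label=""):
    return Signal(fs=FS, values=np.asarray(values, dtype=float), label=label)


class TestPruneChannels:
    def _raw(self, mean, cv, name="S1-D1"):
        rng = np.random.default_rng(0)
        v = mean * (1.0 + (cv / 100.0) * rng.standard_normal(2000))
        return {(name, 760): _sig(np.abs(v)), (name, 850): _sig(np.abs(v))}

    def test_saturated_level_pruned(self):
        raw = {**self._raw(3.0, 1.0, "S1-D1"), **self._raw(1.0, 1.0, "S2-D2")}
        assert prune_channels(raw) == ["S2-D2"]

    def test_high_cv_pruned(self):
        raw = {**self._raw(1.0, 20.0, "S1-D1"), **self._raw(1.0, 5.0, "S2-D2")}
        assert prune_channels(raw) == ["S2-D2"]

    def test_clean_channel_retained(self):
        assert prune_channels(self._raw(1.0, 5.0)) == ["S1-D1"]

    def test_all_pruned_raises(self):
        with pytest.raises(ValueError, match="all channels pruned"):
            prune_channels(self._raw(5.0, 1.0))


class TestIntensityToOd:
    def test_constant_gives_zero(self):
        od = intensity_to_od(_sig(np.full(100, 1.3)))
        assert np.allclose(od.values, 0.0)

    def test_tenth_of_mean_gives_one(self):
        v = np.full(1000, 1.0)
        v[500] = 0.1
        od = intensity_to_od(_sig(v / np.mean(v) * np.mean(v)))
        # the reference is the channel mean, so correct for it explicitly
        expected = -np.log10(0.1 / v.mean())
        assert od.values[500] == pytest.approx(expected, abs=1e-12)

    def test_roundtrip(self):
        rng = np.random.default_rng(1)
        v = np.exp(rng.normal(0, 0.1, 500))
        od = intensity_to_od(_sig(v))
        back = v.mean() * 10.0 ** (-od.values)
        assert np.allclose(back, v, atol=1e-12)

    def test_nonpositive_rejected(self):
        v = np.ones(100)
        v[3] = 0.0
        with pytest.raises(ValueError):
            intensity_to_od(_sig(v))


class TestWaveletMotionCorrect:
    def test_smooth_signal_preserved(self):
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        out = wavelet_motion_correct(_sig(x))
        rms = np.sqrt(np.mean((out.values - x) ** 2)) / np.std(x)
        assert rms < 0.01

    def test_spike_suppressed(self):
        # a fast transient 10x the slow background; the off-spike region
        # excludes the coarse-scale support of the zeroed coefficients
        rng = np.random.default_rng(2)
        t = np.arange(int(600 * FS)) / FS
        x = 0.02 * np.sin(2 * np.pi * 0.02 * t) + rng.normal(0, 0.001, t.size)
        spike_idx = t.size // 2
        spiked = x.copy()
        spiked[spike_idx:spike_idx + 5] += 0.2
        out = wavelet_motion_correct(_sig(spiked))
        residual_spike = out.values[spike_idx:spike_idx + 5] - x[spike_idx:spike_idx + 5]
        assert np.abs(residual_spike).max() < 0.2 * 0.2
        off = np.ones(t.size, dtype=bool)
        off[spike_idx - int(30 * FS):spike_idx + int(30 * FS)] = False
        rms_change = np.sqrt(np.mean((out.values[off] - spiked[off]) ** 2))
        assert rms_change <= 0.05 * np.std(x)

    def test_zero_in_zero_out(self):
        out = wavelet_motion_correct(_sig(np.zeros(2000)))
        assert np.allclose(out.values, 0.0)


class TestBandpassOd:
    def test_cardiac_attenuated(self):
        t = np.arange(int(1200 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass_od(_sig(x))
        mid = slice(int(200 * FS), int(1000 * FS))
        assert 20 * np.log10(np.std(out.values[mid]) * np.sqrt(2)) < -20

    def test_mayer_band_passthrough(self):
        t = np.arange(int(1200 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = bandpass_od(_sig(x))
        mid = slice(int(200 * FS), int(1000 * FS))
        assert abs(20 * np.log10(np.std(out.values[mid]) * np.sqrt(2))) < 1

    def test_constant_removed(self):
        out = bandpass_od(_sig(np.full(5000, 0.3)))
        assert np.abs(out.values).max() < 1e-6


class TestFlagMotion:
    def test_clean_signal_unmasked(self):
        rng = np.random.default_rng(3)
        mask = flag_motion(_sig(rng.normal(0, 0.001, 5000)))
        assert not mask.any()

    def test_large_jump_masked(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 0.001, 5000)
        v[2500:] += 1.0
        mask = flag_motion(_sig(v))
        assert mask[2500]

    def test_mask_extension(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 0.001, 5000)
        v[2500:] += 1.0
        mask = flag_motion(_sig(v), t_mask=2.0)
        ext = int(2.0 * FS)
        assert mask[2500 - ext + 1]


class TestMbll:
    def test_zero_od_zero_conc(self):
        const = OpticalConstants()
        odw = {760: _sig(np.zeros(100)), 850: _sig(np.zeros(100))}
        hbo, hbr = mbll(odw, const, 3.0)
        assert np.allclose(hbo, 0.0) and np.allclose(hbr, 0.0)

    def test_forward_inverse_roundtrip(self):
        const = OpticalConstants()
        rng = np.random.default_rng(4)
        hbo_t = rng.normal(1.0, 0.5, 300)
        hbr_t = rng.normal(-0.3, 0.2, 300)
        odw = {}
        for wl in (760, 850):
            od = (const.extinction[(wl, "HbO")] * hbo_t
                  + const.extinction[(wl, "HbR")] * hbr_t) / 1000.0 \
                * 3.0 * const.dpf[wl]
            odw[wl] = _sig(od)
        hbo, hbr = mbll(odw, const, 3.0)
        assert np.abs(hbo - hbo_t).max() < 1e-10
        assert np.abs(hbr - hbr_t).max() < 1e-10

    def test_hbt_sum_identity(self):
        rng = np.random.default_rng(5)
        hb = HbSeries(hbo={"a": rng.normal(size=50)},
                      hbr={"a": rng.normal(size=50)}, fs=FS)
        assert np.allclose(hb.hbt["a"], hb.hbo["a"] + hb.hbr["a"], atol=1e-12)

    def test_singular_matrix_rejected(self):
        const = OpticalConstants(extinction={
            (760, "HbO"): 1.0, (760, "HbR"): 2.0,
            (850, "HbO"): 2.0, (850, "HbR"): 4.0})
        odw = {760: _sig(np.zeros(10)), 850: _sig(np.zeros(10))}
        with pytest.raises(ValueError, match="singular"):
            mbll(odw, const, 3.0)


class TestVisualRegression:
    def test_exact_proportionality_gives_zero(self):
        rng = np.random.default_rng(6)
        g = rng.normal(size=1000)
        resid = visual_regression(2.0 * g, g)
        assert np.abs(resid).max() < 1e-9

    def test_global_removed_local_kept(self):
        rng = np.random.default_rng(7)
        n = 5000
        local = np.sin(2 * np.pi * 0.02 * np.arange(n) / FS)
        glob = rng.normal(size=n).cumsum()
        glob = (glob - glob.mean()) / glob.std()
        visual = glob + 0.05 * rng.normal(size=n)
        auditory = local + 0.8 * glob
        resid = visual_regression(auditory, visual)
        assert abs(np.corrcoef(resid, glob)[0, 1]) < 0.1
        assert np.corrcoef(resid, local)[0, 1] > 0.9

    def test_zero_variance_visual_passthrough(self):
        a = np.random.default_rng(8).normal(size=100)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = visual_regression(a, np.zeros(100))
        assert np.array_equal(out, a)


def _montage_2ch():
    chans = [Channel(1, 1), Channel(2, 2)]
    return Montage(channels=chans, roi_map={"S1-D1": "LAC", "S2-D2": "VSC"})


def _events(onsets):
    return EventTable(pd.DataFrame({"onset_s": onsets,
                                    "intensity_dBA": [70.9] * len(onsets),
                                    "trial": range(1, len(onsets) + 1)}),
                      intensities=(70.9,), require_balanced=False)


class TestBlockAverageAndRoi:
    def _hb(self, n=int(600 * FS), mask_hit=None):
        hbo = {"S1-D1": np.ones(n), "S2-D2": np.ones(n)}
        hbr = {"S1-D1": -np.ones(n) * 0.3, "S2-D2": -np.ones(n) * 0.3}
        mask = {c: np.zeros(n, dtype=bool) for c in hbo}
        if mask_hit is not None:
            mask["S1-D1"][mask_hit] = True
        return HbSeries(hbo=hbo, hbr=hbr, fs=FS, mask=mask)

    def test_constant_hb_zero_epochs(self):
        ep = block_average(self._hb(), _events([100.0, 300.0]))
        assert np.allclose(ep["S1-D1"]["HbO"].data, 0.0)

    def test_masked_epoch_excluded(self):
        hit = int(300.0 * FS) + 10     # inside (-5, 20) of the 300 s event
        ep = block_average(self._hb(mask_hit=hit), _events([100.0, 300.0]))
        assert np.isnan(ep["S1-D1"]["HbO"].data[1]).all()
        assert not np.isnan(ep["S1-D1"]["HbO"].data[0]).any()
        assert not np.isnan(ep["S2-D2"]["HbO"].data[1]).any()

    def test_hbt_identity_in_epochs(self):
        ep = block_average(self._hb(), _events([100.0]))
        s = ep["S1-D1"]
        assert np.allclose(s["HbT"].data, s["HbO"].data + s["HbR"].data,
                           atol=1e-12)

    def test_roi_single_channel_identity(self):
        ep = block_average(self._hb(), _events([100.0]))
        roi = roi_collapse(ep, _montage_2ch())
        assert np.allclose(roi["LAC"]["HbO"].data, ep["S1-D1"]["HbO"].data,
                           equal_nan=True)

    def test_windowed_means_boxcar_ordering(self):
        n = int(600 * FS)
        t = np.arange(n) / FS
        resp = np.zeros(n)
        on = 100.0
        resp[(t > on + 5) & (t < on + 12)] = 1.0   # early boxcar
        hb = HbSeries(hbo={"S1-D1": resp, "S2-D2": np.zeros(n)},
                      hbr={"S1-D1": np.zeros(n), "S2-D2": np.zeros(n)},
                      fs=FS,
                      mask={c: np.zeros(n, dtype=bool)
                            for c in ("S1-D1", "S2-D2")})
        ep = block_average(hb, _events([on]))
        roi = roi_collapse(ep, _montage_2ch())
        wm = windowed_means(roi)
        tw1 = wm[(wm.roi == "LAC") & (wm.chromophore == "HbO")
                 & (wm.tw == "TW1")]["value"].iloc[0]
        tw2 = wm[(wm.roi == "LAC") & (wm.chromophore == "HbO")
                 & (wm.tw == "TW2")]["value"].iloc[0]
        assert tw1 > tw2
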