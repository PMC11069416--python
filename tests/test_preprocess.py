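"""Optical density, motion correction, filtering, MBLL and CBSI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsync.preprocess import (
    ActivationSignal,
    ConcentrationSignals,
    OpticalDensity,
    QualityThresholds,
    RawIntensity,
    bandpass,
    cbsi,
    channel_quality,
    intensity_to_od,
    mbll_matrix,
    motion_correct_wavelet,
    od_to_concentration,
    preprocess_to_activation,
)

FS = 8.33


def _raw(values):
    values = np.asarray(values, float)
    return RawIntensity(values=values, fs=FS, channel_ids=np.arange(1, values.shape[0] + 1))


def _od(values):
    values = np.asarray(values, float)
    return OpticalDensity(values=values, fs=FS, channel_ids=np.arange(1, values.shape[0] + 1))


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self):
        od = intensity_to_od(_raw(np.full((2, 100, 3), 1000.0)))
        np.testing.assert_allclose(od.values, 0.0, atol=1e-14)

    def test_efold_sample_gives_unit_od(self):
        vals = np.full((1, 1000, 3), 1.0)
        od = intensity_to_od(_raw(vals))
        mean = vals[0, :, 0].mean()
        vals2 = vals.copy()
        # one sample at mean * e^-1 (mean barely changes with 1000 samples;
        # recompute against the realised mean)
        vals2[0, 500, :] = np.exp(-1.0)
        od2 = intensity_to_od(_raw(vals2))
        expected = 1.0 + np.log(vals2[0, :, 0].mean())
        np.testing.assert_allclose(od2.values[0, 500, :], expected, rtol=1e-10)

    def test_matches_direct_formula(self, rng):
        vals = rng.uniform(100, 5000, (3, 256, 3))
        od = intensity_to_od(_raw(vals))
        direct = -np.log(vals / vals.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(od.values, direct, atol=1e-12)

    def test_nonpositive_rejected_with_location(self):
        vals = np.full((2, 50, 3), 10.0)
        vals[1, 7, 2] = 0.0
        with pytest.raises(ValueError, match="channel 2.*sample 7"):
            intensity_to_od(_raw(vals))


class TestMotionCorrection:
    def test_smooth_signal_nearly_untouched(self):
        t = np.arange(2048) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        od = _od(x[None, :, None] * np.ones((1, 1, 3)))
        out = motion_correct_wavelet(od)
        rms_in = np.sqrt(np.mean(x**2))
        rms_diff = np.sqrt(np.mean((out.values[0, :, 0] - x) ** 2))
        assert rms_diff < 0.05 * rms_in

    def test_injected_spike_suppressed(self, rng):
        # motion bump of ~1.8 s support (SD 0.3 s), peak 10x the signal SD
        n = 2048
        x = rng.standard_normal(n) * 0.01
        k = 900
        spike = 10 * x.std()
        t = np.arange(n)
        bump = spike * np.exp(-0.5 * ((t - k) / (0.3 * FS)) ** 2)
        out = motion_correct_wavelet(_od(np.tile((x + bump)[None, :, None], (1, 1, 3))))
        residual = abs(out.values[0, k, 0] - x[k])
        assert residual < 0.1 * spike
        # even a single-sample delta is substantially suppressed
        xs = x.copy()
        xs[k] += spike
        out2 = motion_correct_wavelet(_od(np.tile(xs[None, :, None], (1, 1, 3))))
        assert abs(out2.values[0, k, 0] - x[k]) < 0.3 * spike

    def test_zero_signal_stays_zero(self):
        out = motion_correct_wavelet(_od(np.zeros((2, 512, 3))))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)


class TestBandpass:
    """FFT-based gain measurements of the zero-phase Butterworth filter."""

    @staticmethod
    def _gain(freq, n=6000):
        t = np.arange(n) / FS
        x = np.cos(2 * np.pi * freq * t) if freq > 0 else np.ones(n)
        out = bandpass(_od(np.tile(x[None, :, None], (1, 1, 3))))
        y = out.values[0, :, 0]
        if freq == 0:
            return np.abs(y).max()
        # amplitude at the driven frequency via the discrete Fourier sum
        core = slice(n // 4, 3 * n // 4)  # steady-state section
        tt = t[core]
        amp = 2 * np.abs(np.mean(y[core] * np.exp(-2j * np.pi * freq * tt)))
        return amp

    def test_dc_rejected(self):
        assert self._gain(0.0) < 1e-6

    def test_passband_gain(self):
        assert self._gain(0.05) > 0.95

    def test_stopband_gain(self):
        assert self._gain(1.1) < 0.01

    def test_nyquist_edge_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_od(np.ones((1, 100, 3))), lo=0.01, hi=5.0)

    def test_out_of_band_power_negligible(self, rng):
        x = rng.standard_normal((1, 8192, 3))
        out = bandpass(_od(x))
        y = out.values[0, :, 0]
        f = np.fft.rfftfreq(len(y), 1 / FS)
        p = np.abs(np.fft.rfft(y)) ** 2
        outside = (f < 0.005) | (f > 0.5)
        assert p[outside].sum() < 0.01 * p.sum()


class TestMBLL:
    def test_zero_od_zero_concentration(self):
        conc = od_to_concentration(_od(np.zeros((2, 64, 3))))
        np.testing.assert_allclose(conc.hbo, 0.0, atol=1e-15)
        np.testing.assert_allclose(conc.hbr, 0.0, atol=1e-15)

    def test_roundtrip_recovery(self, rng):
        A = mbll_matrix()
        hbo = np.full((1, 128), 1.0) + 0.1 * rng.standard_normal((1, 128))
        hbr = np.full((1, 128), -0.3) + 0.05 * rng.standard_normal((1, 128))
        od_vals = np.einsum("wk,ctk->ctw", A.T.copy().T, np.stack([hbo, hbr], axis=-1))
        conc = od_to_concentration(_od(od_vals))
        np.testing.assert_allclose(conc.hbo, hbo, rtol=1e-9)
        np.testing.assert_allclose(conc.hbr, hbr, rtol=1e-9)

    def test_linearity(self, rng):
        od_vals = rng.standard_normal((2, 64, 3)) * 0.01
        c1 = od_to_concentration(_od(od_vals))
        c2 = od_to_concentration(_od(2 * od_vals))
        np.testing.assert_allclose(c2.hbo, 2 * c1.hbo, rtol=1e-12)
        np.testing.assert_allclose(c2.hbr, 2 * c1.hbr, rtol=1e-12)


class TestCBSI:
    @staticmethod
    def _conc(hbo, hbr):
        hbo = np.atleast_2d(hbo)
        hbr = np.atleast_2d(hbr)
        return ConcentrationSignals(
            hbo=hbo, hbr=hbr, fs=FS, channel_ids=np.arange(1, hbo.shape[0] + 1)
        )

    def test_anticorrelated_closed_form(self, rng):
        hbo = rng.standard_normal(200)
        act = cbsi(self._conc(hbo, -hbo))
        assert act.alpha[0] == pytest.approx(1.0)
        np.testing.assert_allclose(act.values[0], hbo, atol=1e-12)

    def test_correlated_cancels(self, rng):
        hbo = rng.standard_normal(200)
        act = cbsi(self._conc(hbo, hbo))
        assert act.alpha[0] == pytest.approx(1.0)
        np.testing.assert_allclose(act.values[0], 0.0, atol=1e-12)

    def test_matches_direct_formula(self, rng):
        hbo = rng.standard_normal((3, 150))
        hbr = rng.standard_normal((3, 150))
        act = cbsi(self._conc(hbo, hbr))
        for c in range(3):
            alpha = hbo[c].std() / hbr[c].std()
            np.testing.assert_allclose(act.values[c], (hbo[c] - alpha * hbr[c]) / 2, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_in_hbr(self, k):
        rng = np.random.default_rng(7)
        hbo = rng.standard_normal(100)
        hbr = rng.standard_normal(100)
        a1 = cbsi(self._conc(hbo, hbr))
        a2 = cbsi(self._conc(hbo, k * hbr))
        np.testing.assert_allclose(a1.values, a2.values, rtol=1e-9, atol=1e-12)

    def test_degenerate_hbr_flagged(self, rng):
        hbo = rng.standard_normal((2, 100))
        hbr = np.vstack([rng.standard_normal(100), np.zeros(100)])
        act = cbsi(self._conc(hbo, hbr))
        assert not act.degenerate[0] and act.degenerate[1]
        assert np.isnan(act.alpha[1])


class TestChannelQuality:
    @staticmethod
    def _channel(heartbeat_amp, n=1500, rail=None, rng=None):
        rng = rng or np.random.default_rng(0)
        t = np.arange(n) / FS
        base = 1000.0 * (1 + 0.01 * rng.standard_normal((n, 3)))
        hb = heartbeat_amp * 1000.0 * np.sin(2 * np.pi * 1.1 * t)[:, None]
        vals = base + hb
        if rail is not None:
            vals[:] = rail
        return vals[None, :, :]

    def test_heartbeat_channel_included(self):
        raw = _raw(self._channel(0.02))
        rep = channel_quality(raw)
        assert bool(rep["included"].iloc[0])

    def test_flatlined_channel_excluded(self):
        raw = _raw(self._channel(0.0, rail=4096.0))
        rep = channel_quality(raw, thresholds=QualityThresholds(saturation_value=4096.0))
        assert bool(rep["saturation_flag"].iloc[0])
        assert not bool(rep["included"].iloc[0])

    def test_no_heartbeat_excluded(self):
        raw = _raw(self._channel(0.0))
        rep = channel_quality(raw)
        assert not bool(rep["included"].iloc[0])
        assert rep["heartbeat_snr_db"].iloc[0] < 4.0


class TestPipelineComposition:
    def test_shapes_preserved_and_order_fixed(self, small_session):
        session, _ = small_session
        raw = session.raw["A"]
        act = preprocess_to_activation(raw)
        assert act.values.shape == (raw.n_channels, raw.n_samples)
        # the convenience wrapper must equal the explicit staged composition
        od = intensity_to_od(raw)
        assert od.values.shape == raw.values.shape
        od = motion_correct_wavelet(od)
        assert od.values.shape == raw.values.shape
        od = bandpass(od)
        conc = od_to_concentration(od)
        manual = cbsi(conc)
        np.testing.assert_allclose(act.values, manual.values, atol=1e-12)

    def test_mbll_roundtrip_property_random(self, rng):
        A = mbll_matrix()
        for _ in range(10):
            conc_true = rng.standard_normal((2, 2, 64))  # (species, ch, t)
            od_vals = np.einsum("wk,kct->ctw", A, conc_true)
            conc = od_to_concentration(_od(od_vals))
            np.testing.assert_allclose(conc.hbo, conc_true[0], rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(conc.hbr, conc_true[1], rtol=1e-9, atol=1e-12)
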