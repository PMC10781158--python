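"""Spectral estimation, coherence and the alpha index."""

import dataclasses

import numpy as np
import pytest

from barovar.beats import BeatSeries, SegmentSet
from barovar.simulate import simulate_beat_series, study_presets
from barovar.variability import (
    ResampledSeries,
    SpectralOptions,
    alpha_index,
    band_power,
    bpv_endpoints,
    psd_and_coherence,
    resample_beat_series,
    time_domain_bpv,
)


def _beats_from_values(t, values, pi_ms):
    return BeatSeries(t=t, sbp=values, pi=np.full(len(t), pi_ms))


def _noise_series(seed, n=3000, fs=10.0, scale=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, scale, n)
    x -= x.mean()
    return ResampledSeries(values=x, fs_out=fs)


class TestTimeDomain:
    def test_mean_of_per_segment_sds(self):
        segs = []
        for sd_target, seed in ((5.0, 1), (6.0, 2), (7.0, 3)):
            rng = np.random.default_rng(seed)
            v = rng.normal(120.0, 1.0, 400)
            v = 120.0 + (v - v.mean()) / v.std(ddof=1) * sd_target  # exact SD
            t = np.arange(400) * 0.2
            segs.append(_beats_from_values(t, v, 200.0))
        td = time_domain_bpv(SegmentSet(segments=segs, window_s=80.0, count=3))
        assert td.sd_sbp == pytest.approx(6.0, abs=1e-9)
        assert td.var_sbp == pytest.approx(np.mean([25.0, 36.0, 49.0]), abs=1e-9)

    def test_constant_pressure_has_zero_variability(self):
        t = np.arange(100) * 0.2
        seg = _beats_from_values(t, np.full(100, 130.0), 200.0)
        td = time_domain_bpv(SegmentSet(segments=[seg], window_s=20.0, count=1))
        assert td.sd_sbp == 0.0 and td.var_sbp == 0.0


class TestResampling:
    def test_identity_on_already_uniform_beats(self):
        # beats on the output grid: spline evaluation reproduces them exactly
        t = np.arange(0.0, 30.0, 0.1)
        rng = np.random.default_rng(0)
        v = 3.0 * np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.2, t.size)
        b = _beats_from_values(t, v, 100.0)
        r = resample_beat_series(b, fs_out=10.0, do_detrend=False)
        assert np.allclose(r.values[: t.size], v, atol=1e-6)

    def test_linear_ramp_removed_by_detrending(self):
        t = np.arange(0.0, 60.0, 0.17)
        b = _beats_from_values(t, 100.0 + 0.5 * t, 170.0)
        r = resample_beat_series(b, fs_out=10.0)
        assert abs(np.mean(r.values)) < 1e-8
        slope = np.polyfit(np.arange(r.values.size) / 10.0, r.values, 1)[0]
        assert abs(slope) < 1e-8

    def test_dominant_frequency_preserved(self):
        cfg_t = np.cumsum(np.full(1800, 0.17))
        v = 150.0 + 4.0 * np.sin(2 * np.pi * 0.4 * cfg_t)
        b = _beats_from_values(cfg_t, v, 170.0)
        r = resample_beat_series(b, fs_out=10.0)
        spec = np.abs(np.fft.rfft(r.values))
        freqs = np.fft.rfftfreq(r.values.size, d=0.1)
        assert freqs[np.argmax(spec)] == pytest.approx(0.4, abs=0.01)

    def test_nyquist_guard(self):
        t = np.arange(0.0, 30.0, 0.17)
        b = _beats_from_values(t, np.full(t.size, 120.0), 170.0)
        with pytest.raises(ValueError, match="Nyquist below LF band"):
            resample_beat_series(b, fs_out=1.0)


class TestSpectra:
    def test_sinusoid_band_power(self):
        t = np.arange(3000) / 10.0
        x = 3.0 * np.sin(2 * np.pi * 0.4 * t)
        sbp = ResampledSeries(values=x, fs_out=10.0)
        sp = psd_and_coherence(sbp, sbp)
        assert sp.lf_power_sbp == pytest.approx(4.5, rel=0.05)

    def test_proportional_series_have_unit_coherence(self):
        x = _noise_series(1)
        y = ResampledSeries(values=0.7 * x.values, fs_out=10.0)
        sp = psd_and_coherence(y, x)
        signal = sp.psd_sbp > 1e-12
        assert np.allclose(sp.coh2[signal], 1.0, atol=1e-9)

    def test_psd_integral_matches_variance_welch(self):
        x = _noise_series(2)
        sp = psd_and_coherence(x, x)
        total = np.trapezoid(sp.psd_sbp, sp.freqs)
        assert total == pytest.approx(np.var(x.values), rel=0.05)

    def test_coherence_bounded(self, so_beats):
        seg = so_beats.window(0.0, 300.0)
        r_sbp = resample_beat_series(seg, signal="sbp")
        r_pi = resample_beat_series(seg, signal="pi")
        sp = psd_and_coherence(r_pi, r_sbp)
        assert np.all(sp.coh2 >= 0.0) and np.all(sp.coh2 <= 1.0)

    def test_too_short_series_errors_with_minimum_duration(self):
        x = _noise_series(3, n=100)
        with pytest.raises(ValueError, match="too short"):
            psd_and_coherence(x, x)

    def test_mismatched_series_rejected(self):
        x = _noise_series(4, n=3000)
        y = _noise_series(5, n=2999)
        with pytest.raises(ValueError, match="equal length"):
            psd_and_coherence(x, y)


class TestAlphaIndex:
    def test_alpha_equals_gain_under_exact_proportionality(self):
        x = _noise_series(6)
        for g in (0.3, 0.5, 1.0):
            y = ResampledSeries(values=g * x.values, fs_out=10.0)
            res = alpha_index(psd_and_coherence(y, x))
            assert res.valid
            assert res.alpha == pytest.approx(g, abs=1e-9)

    def test_independent_noise_fails_gate(self):
        x = _noise_series(7)
        y = _noise_series(8)
        res = alpha_index(psd_and_coherence(y, x))
        assert not res.valid
        assert res.alpha is None
        assert "coherence" in res.reason

    def test_alpha_scales_linearly_with_each_channel(self):
        x = _noise_series(9)
        y = ResampledSeries(values=0.5 * x.values, fs_out=10.0)
        base = alpha_index(psd_and_coherence(y, x)).alpha
        c = 3.0
        y_scaled = ResampledSeries(values=c * y.values, fs_out=10.0)
        x_scaled = ResampledSeries(values=c * x.values, fs_out=10.0)
        assert alpha_index(psd_and_coherence(y_scaled, x)).alpha == pytest.approx(c * base)
        assert alpha_index(psd_and_coherence(y, x_scaled)).alpha == pytest.approx(base / c)

    def test_alpha_monotone_in_gain_on_noise_free_inputs(self, so_sim):
        alphas = []
        for g in (0.2, 0.5, 0.9):
            cfg = dataclasses.replace(
                so_sim, duration_s=300.0, gain=g, noise_sd_pi=0.0, seed=11
            )
            b = simulate_beat_series(cfg)
            opts = SpectralOptions(n_windows=1)
            alphas.append(bpv_endpoints(b, opts)["alpha"])
        assert alphas == sorted(alphas)

    def test_zero_pressure_power_reported(self):
        freqs = np.linspace(0, 5, 100)
        from barovar.variability import SpectralResult

        sp = SpectralResult(
            freqs=freqs,
            psd_sbp=np.zeros(100),
            psd_pi=np.ones(100),
            cross_spectrum=np.zeros(100, dtype=complex),
            coh2=np.ones(100),
            lf_band=(0.2, 0.75),
            lf_power_sbp=0.0,
            lf_power_pi=1.0,
        )
        res = alpha_index(sp)
        assert not res.valid and res.reason == "no pressure power in band"


def test_pipeline_endpoints_match_preset_targets(so_beats):
    p = study_presets()["SO"]
    e = bpv_endpoints(so_beats)
    assert e["sd_sbp"] == pytest.approx(p.target_sd_sbp, rel=0.15)
    assert e["alpha_valid"]
    assert e["alpha"] == pytest.approx(p.target_alpha, rel=0.15)


def test_band_power_requires_bins():
    with pytest.raises(ValueError, match="bins"):
        band_power(np.array([0.0, 5.0]), np.array([1.0, 1.0]), (0.2, 0.75))
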