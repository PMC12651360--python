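"""Spectral stage: Burg estimation, PSD grid, onset, resonances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.regression.linear_model import yule_walker

from vibrofirm import sigproc, synthgen
from vibrofirm.sigproc import (ARModel, DegenerateSignalError,
                               InsufficientPeaksError, NoOnsetError,
                               SegmentBoundsError, SigprocError, Spectrum,
                               ar_psd, burg_ar, correlation_profile,
                               detect_onset, elasticity_index,
                               extract_segment, find_resonances)


def simulate_ar2(n, seed, phi=(1.0, -0.5)):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n + 100)
    x = np.zeros(n + 100)
    for i in range(2, n + 100):
        x[i] = phi[0] * x[i - 1] + phi[1] * x[i - 2] + e[i]
    return x[100:]


class TestBurg:
    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(65536)
        m = burg_ar(x, 4, sampling_rate=1000.0)
        assert np.all(np.abs(m.coefficients) < 0.05)
        assert m.noise_variance == pytest.approx(np.var(x), rel=0.05)

    def test_ar2_recovery_and_yule_walker_agreement(self):
        """20 seeds: Burg within 0.05 of truth and 0.02 of Yule-Walker."""
        for seed in range(20):
            x = simulate_ar2(8192, seed)
            m = burg_ar(x, 2, sampling_rate=1000.0)
            # x[n] = 1.0 x[n-1] - 0.5 x[n-2] + e  ->  a = (-1.0, 0.5)
            np.testing.assert_allclose(m.coefficients, [-1.0, 0.5], atol=0.05)
            rho, _ = yule_walker(x, order=2, method="mle")
            np.testing.assert_allclose(m.coefficients, -rho, atol=0.02)

    def test_constant_segment_rejected(self):
        with pytest.raises(DegenerateSignalError):
            burg_ar(np.ones(100), 4)

    def test_order_bounds(self):
        with pytest.raises(SigprocError):
            burg_ar(np.random.default_rng(0).standard_normal(10), 10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 12))
    def test_minimum_phase_on_random_signals(self, seed, order):
        """Reflection-coefficient clipping implies all AR roots inside the
        unit circle for arbitrary inputs."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(256) + np.sin(np.arange(256) * rng.uniform(0, 3))
        m = burg_ar(x, order, sampling_rate=1000.0)
        roots = np.roots(np.concatenate([[1.0], m.coefficients]))
        assert np.all(np.abs(roots) < 1.0 + 1e-8)
        assert m.noise_variance >= 0


class TestArPsd:
    def test_default_grid_is_2623_points_over_5_khz(self):
        m = ARModel(order=2, coefficients=np.array([-0.5, 0.1]),
                    noise_variance=1.0, sampling_rate=312500.0)
        spec = ar_psd(m)
        assert len(spec) == 2623
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[-1] == 5000.0
        step = np.diff(spec.frequencies)
        assert np.allclose(step, 5000.0 / 2622)

    def test_white_noise_model_gives_flat_2sigma2_over_fs(self):
        m = ARModel(order=0, coefficients=np.zeros(0), noise_variance=3.0,
                    sampling_rate=10000.0)
        spec = ar_psd(m, f_max=5000.0, n_points=100)
        np.testing.assert_allclose(spec.power, 2 * 3.0 / 10000.0)

    def test_low_pass_ar1_is_strictly_decreasing(self):
        m = ARModel(order=1, coefficients=np.array([-0.9]),
                    noise_variance=1.0, sampling_rate=312500.0)
        spec = ar_psd(m)
        assert np.all(np.diff(spec.power) < 0)

    def test_f_max_beyond_nyquist_rejected(self):
        m = ARModel(order=1, coefficients=np.array([-0.5]),
                    noise_variance=1.0, sampling_rate=8000.0)
        with pytest.raises(SigprocError):
            ar_psd(m, f_max=5000.0)

    def test_white_noise_psd_level_matches_variance(self):
        """Burg-fitted white noise: mean PSD level ~= 2 sigma^2/fs (10%)."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(65536)
        m = burg_ar(x, 4, sampling_rate=10000.0)
        spec = ar_psd(m, f_max=5000.0, n_points=512)
        assert np.mean(spec.power) == pytest.approx(2 * np.var(x) / 10000.0,
                                                    rel=0.10)


class TestOnsetAndSegment:
    def _record(self, x, fs=1000.0):
        return synthgen.VibrationRecord(
            fruit_id="f", replicate_id="r", cultivar="c", firmness=1.0,
            mass=0.2, sampling_rate=fs, onset_index=0,
            samples=np.asarray(x, dtype=float))

    def test_impulse_onset_found(self):
        x = np.zeros(2000)
        x[1234] = 1.0
        rec = self._record(x)
        assert detect_onset(rec, noise_window=0.5, k=5.0, m=1) == 1234

    def test_pure_noise_rarely_triggers(self):
        """False-positive check: stationary noise, k=8, m=10."""
        false_pos = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rec = self._record(rng.standard_normal(2000))
            try:
                detect_onset(rec, noise_window=0.5, k=8.0, m=10)
                false_pos += 1
            except NoOnsetError:
                pass
        assert false_pos <= 1

    def test_simulated_onset_within_5_ms(self, profiles):
        # full-rate acquisition: the m=10 consecutive-sample rule spans
        # 32 us there, well under a half-period of the first mode
        cfg = synthgen.SyntheticConfig()
        rec = synthgen.simulate_signal(profiles["hujing"], 2.01, 0.2,
                                       cfg, seed=9)
        onset = detect_onset(rec)
        assert abs(onset - rec.onset_index) <= 0.005 * cfg.sampling_rate

    def test_record_shorter_than_noise_window_rejected(self):
        rec = self._record(np.zeros(100))
        with pytest.raises(SigprocError):
            detect_onset(rec, noise_window=0.5)

    def test_segment_length_at_full_rate(self):
        rec = self._record(np.zeros(937_500), fs=312500.0)
        seg = extract_segment(rec, onset=468_750, pre=1.5, post=1.5)
        assert len(seg) == 937_500

    def test_segment_length_small(self):
        rec = self._record(np.zeros(2000), fs=1000.0)
        assert len(extract_segment(rec, onset=600, pre=0.5, post=0.5)) == 1000

    def test_segment_bounds_enforced(self):
        rec = self._record(np.zeros(2000), fs=1000.0)
        with pytest.raises(SegmentBoundsError):
            extract_segment(rec, onset=0, pre=1.5, post=0.1)
        with pytest.raises(SegmentBoundsError):
            extract_segment(rec, onset=1900, pre=0.1, post=1.5)


class TestResonances:
    def test_cultivar_mean_resonances_recovered(self, profiles,
                                                reduced_config):
        """Simulated record at the cultivar mean firmness: detected (f1, f2)
        within 10 Hz of the profile anchors."""
        prof = profiles["jinqiuhong"]
        rec = synthgen.simulate_signal(prof, prof.mean_firmness, 0.2,
                                       reduced_config, seed=3)
        m = burg_ar(rec.samples[rec.onset_index:], 50,
                    sampling_rate=reduced_config.sampling_rate)
        res = find_resonances(ar_psd(m))
        assert abs(res.f1 - 900.3) <= 10
        assert abs(res.f2 - 1401.9) <= 10

    def test_monotone_spectrum_has_no_peaks(self):
        f = np.linspace(0, 5000, 500)
        spec = Spectrum(frequencies=f, power=np.exp(-f / 1000))
        with pytest.raises(InsufficientPeaksError):
            find_resonances(spec)

    def test_two_delta_peaks_returned_in_order(self):
        f = np.linspace(0, 5000, 501)
        p = np.full(501, 1e-6)
        p[80] = 1.0
        p[200] = 0.5
        spec = Spectrum(frequencies=f, power=p)
        res = find_resonances(spec)
        assert res.f1 == f[80]
        assert res.f2 == f[200]


class TestElasticityIndex:
    def test_values(self):
        assert elasticity_index(1.0, 1.0) == 1.0
        assert elasticity_index(1401.9, 0.2) == pytest.approx(393_064.722)

    def test_quadratic_homogeneity(self):
        assert elasticity_index(2 * 700.0, 0.3) == \
            pytest.approx(4 * elasticity_index(700.0, 0.3))

    def test_nonpositive_rejected(self):
        with pytest.raises(SigprocError):
            elasticity_index(0.0, 0.2)


class TestCorrelationProfile:
    def _spectra(self, P, f=None):
        f = np.linspace(0, 100, P.shape[1]) if f is None else f
        return [Spectrum(frequencies=f, power=row) for row in P]

    def test_perfect_correlation_bin(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(0.1, 1.0, (10, 5))
        firmness = P[:, 2].copy()
        prof = correlation_profile(self._spectra(P), firmness)
        assert prof.r[2] == pytest.approx(1.0)

    def test_constant_bin_flagged_zero(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(0.1, 1.0, (8, 4))
        P[:, 1] = 0.7
        prof = correlation_profile(self._spectra(P), rng.uniform(1, 5, 8))
        assert prof.r[1] == 0.0
        assert prof.degenerate[1]

    def test_mismatched_grids_rejected(self):
        f1 = np.linspace(0, 100, 5)
        f2 = np.linspace(0, 200, 5)
        s1 = Spectrum(frequencies=f1, power=np.ones(5))
        s2 = Spectrum(frequencies=f2, power=np.ones(5))
        with pytest.raises(SigprocError):
            correlation_profile([s1, s2, s1], np.array([1.0, 2.0, 3.0]))

    def test_highband_correlates_more_than_resonance_band(self, full_samples):
        """Pooled per-bin correlation: the injected high band near 3 kHz is
        positively correlated with firmness and beats the resonance region."""
        spectra = [s.spectrum for s in full_samples]
        firmness = np.array([s.firmness for s in full_samples])
        prof = correlation_profile(spectra, firmness)
        f = prof.frequencies
        hi = prof.r[(f >= 2900) & (f <= 3100)].mean()
        lo = prof.r[(f >= 900) & (f <= 1100)].mean()
        assert hi > 0
        assert hi > lo
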