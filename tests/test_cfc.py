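"""Cross-frequency coupling: filters, analytic signals, composite z."""
import numpy as np
import pytest
from scipy import stats

from thetagamma import cfc

FS = 1000.0


def _tone(freq, duration_ms=4000.0, amp=1.0, fs=FS):
    t = np.arange(0, duration_ms, 1000.0 / fs)
    return t, amp * np.sin(2 * np.pi * freq * t / 1000.0)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        t, x = _tone(50.0)
        y = cfc.bandpass_gamma(x, FS)
        core = slice(500, -500)
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        for f in (5.0, 150.0):
            t, x = _tone(f)
            y = cfc.bandpass_gamma(x, FS)
            core = slice(500, -500)
            assert np.max(np.abs(y[core])) < 0.1

    def test_linearity(self):
        _, a = _tone(40.0)
        _, b = _tone(60.0)
        y = cfc.bandpass_gamma(a + b, FS)
        np.testing.assert_allclose(
            y, cfc.bandpass_gamma(a, FS) + cfc.bandpass_gamma(b, FS),
            atol=1e-9)

    def test_band_beyond_nyquist_rejected(self):
        _, x = _tone(50.0)
        with pytest.raises(ValueError):
            cfc.bandpass_gamma(x, 100.0, band=(30.0, 80.0))


class TestAnalytic:
    def test_pure_tone_amplitude(self):
        _, x = _tone(50.0, amp=2.7)
        a = cfc.analytic(x)
        core = slice(200, -200)
        np.testing.assert_allclose(a.amplitude[core], 2.7, rtol=0.01)

    def test_phase_advances_two_pi_per_cycle(self):
        _, x = _tone(50.0)
        ph = np.unwrap(cfc.analytic(x).phase)
        cycles = (ph[-200] - ph[200]) / (2 * np.pi)
        dt_cycles = 50.0 * (len(x) - 400) / FS
        assert cycles == pytest.approx(dt_cycles, rel=0.01)

    def test_am_envelope_recovered(self):
        # amplitude-modulated tone: envelope recovered within 2%
        t = np.arange(0, 4000.0, 1.0)
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
        x = env * np.sin(2 * np.pi * 50.0 * t / 1000.0)
        a = cfc.analytic(x)
        core = slice(300, -300)
        np.testing.assert_allclose(a.amplitude[core], env[core], rtol=0.02)


class TestCompositeZ:
    def _phases(self, n=8000, f=4.0):
        t = np.arange(n)
        return 2 * np.pi * f * t / 1000.0

    def test_constant_amplitude_mean_vector_vanishes(self):
        ph = np.angle(np.exp(1j * self._phases()))
        z = cfc.composite_z(np.full(ph.size, 3.0), ph)
        assert cfc.mean_vector_norm(z) < 0.02 * 3.0

    def test_coupled_amplitude_points_at_preferred_phase(self):
        raw = self._phases()
        ph = np.angle(np.exp(1j * raw))
        preferred = -np.pi / 2
        amp = 2.0 + 1.0 * np.cos(raw - preferred)
        z = cfc.composite_z(amp, ph)
        mv = cfc.mean_vector(z)
        assert abs(np.angle(mv) - preferred) < 0.05
        assert abs(mv) > 0.3

    def test_norm_invariant_under_global_rotation(self):
        raw = self._phases()
        amp = 2.0 + np.cos(raw)
        ph = np.angle(np.exp(1j * raw))
        n1 = cfc.mean_vector_norm(cfc.composite_z(amp, ph))
        ph_rot = np.angle(np.exp(1j * (raw + 1.234)))
        n2 = cfc.mean_vector_norm(cfc.composite_z(amp, ph_rot))
        assert n1 == pytest.approx(n2, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cfc.composite_z(np.ones(10), np.ones(11))

    def test_surrogates_bound_uncoupled_norm(self, rng):
        # amplitude independent of phase: the observed norm is typical of
        # the surrogate distribution; coupled amplitude exceeds it
        raw = self._phases()
        ph = np.angle(np.exp(1j * raw))
        amp0 = 2.0 + 0.5 * rng.standard_normal(ph.size)
        sur0 = cfc.surrogate_norms(amp0, ph, 200, rng)
        assert cfc.mean_vector_norm(cfc.composite_z(amp0, ph)) < \
            np.percentile(sur0, 99)
        amp1 = 2.0 + np.cos(raw)
        sur1 = cfc.surrogate_norms(amp1, ph, 200, rng)
        assert cfc.mean_vector_norm(cfc.composite_z(amp1, ph)) > \
            np.percentile(sur1, 99)


class TestPolarHistogram:
    def test_total_conserved(self, rng):
        z = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        counts, _, _ = cfc.polar_histogram(z)
        assert counts.sum() == 500

    def test_identical_samples_single_bin(self):
        z = np.full(50, 1.0 * np.exp(1j * 0.7))
        counts, _, _ = cfc.polar_histogram(z)
        assert (counts > 0).sum() == 1
        assert counts.max() == 50

    def test_uniform_phases_pass_chi_square(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 20000)
        z = np.exp(1j * ph)
        counts, _, _ = cfc.polar_histogram(z, n_phase_bins=16)
        phase_counts = counts.sum(axis=1)
        _, p = stats.chisquare(phase_counts)
        assert p > 0.01


class TestPeakTrough:
    def test_trough_preferring_coupling_detected(self):
        raw = 2 * np.pi * 4.0 * np.arange(16000) / 1000.0
        ph = np.angle(np.exp(1j * raw))
        amp = 2.0 - np.sin(raw)  # max at the trough (-pi/2)
        z = cfc.composite_z(amp, ph)
        pk, tr = cfc.peak_and_trough_amplitudes(z)
        assert tr.mean() > pk.mean()

    def test_symmetric_case_balanced(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 40000)
        amp = 2.0 + 0.1 * rng.standard_normal(40000)
        z = cfc.composite_z(amp, ph)
        pk, tr = cfc.peak_and_trough_amplitudes(z)
        assert abs(pk.mean() - tr.mean()) < 0.02

    def test_window_widening_monotone_in_count(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 5000)
        z = cfc.composite_z(np.ones(5000), ph)
        n = [cfc.peak_and_trough_amplitudes(z, w)[0].size
             for w in (0.2, 0.5, 1.0, 2.0)]
        assert n == sorted(n)


class TestGammaFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(shape=2.0, scale=3.0, size=10_000)
        k, theta = cfc.fit_gamma_dist(x)
        assert k == pytest.approx(2.0, rel=0.05)
        assert theta == pytest.approx(3.0, rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(43)
        x = rng.gamma(2.5, 1.5, 5000)
        k1, t1 = cfc.fit_gamma_dist(x)
        k2, t2 = cfc.fit_gamma_dist(10.0 * x)
        assert k2 == pytest.approx(k1, rel=1e-6)
        assert t2 == pytest.approx(10.0 * t1, rel=1e-6)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            cfc.fit_gamma_dist(np.full(100, 2.0))
        with pytest.raises(ValueError):
            cfc.fit_gamma_dist(np.array([1.0, -2.0, 3.0]))


class TestFrequencyTrack:
    def test_stationary_tone_constant_track(self):
        _, x = _tone(55.0, duration_ms=6000.0)
        _, track = cfc.peak_gamma_frequency_track(x, FS)
        assert np.all(np.abs(track - 55.0) < 4.0)

    def test_chirp_followed(self):
        from scipy.signal import chirp
        t = np.arange(0, 6000.0, 1.0)
        x = chirp(t / 1000.0, f0=40.0, t1=6.0, f1=60.0)
        tt, track = cfc.peak_gamma_frequency_track(x, FS)
        expect = 40.0 + (60.0 - 40.0) * tt / 6000.0
        assert np.corrcoef(track, expect)[0, 1] > 0.95
        assert np.max(np.abs(track - expect)) < 8.0

    def test_track_confined_to_band(self, rng):
        x = rng.standard_normal(4000)
        _, track = cfc.peak_gamma_frequency_track(x, FS)
        assert track.min() >= 30.0 and track.max() <= 80.0

    def test_centroid_statistic_locates_tone(self):
        _, x = _tone(55.0, duration_ms=6000.0)
        _, track = cfc.peak_gamma_frequency_track(x, FS,
                                                  statistic="centroid")
        assert np.all(np.abs(track - 55.0) < 5.0)

    def test_unknown_statistic_rejected(self):
        _, x = _tone(55.0)
        with pytest.raises(ValueError):
            cfc.peak_gamma_frequency_track(x, FS, statistic="median")


class TestEnvelopeCorrelation:
    def test_anti_phase_envelope(self):
        t = np.arange(0, 4000.0, 1.0)
        theta = np.sin(2 * np.pi * 4.0 * t / 1000.0)
        assert cfc.theta_gamma_envelope_correlation(theta, -theta) == \
            pytest.approx(-1.0)

    def test_independent_signals_uncorrelated(self, rng):
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000)
        assert abs(cfc.theta_gamma_envelope_correlation(a, b)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cfc.theta_gamma_envelope_correlation(np.ones(10), np.ones(10))

    def test_lag_estimator_recovers_shift(self):
        t = np.arange(0, 8000.0, 1.0)
        theta = np.sin(2 * np.pi * 4.0 * t / 1000.0)
        lag_true = 40.0
        env = -np.sin(2 * np.pi * 4.0 * (t - lag_true) / 1000.0)
        got = cfc.envelope_lag(theta, env, FS, max_lag_ms=120.0)
        assert got == pytest.approx(lag_true, abs=2.0)
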