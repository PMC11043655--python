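"""The surrogate-normalized mean-vector-length estimator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pacgrid import (
    BandPair,
    DegenerateSurrogateError,
    PacParameterError,
    RegionalTimeSeries,
    amplitude_series,
    bandpass,
    composite_signal,
    modulation_sideband_bands,
    multiband_amplitude_series,
    normalized_pac,
    phase_series,
    raw_mean_vector,
    surrogate_mvls,
)
from pacgrid.experiments import seeded_band_pair
from pacgrid.pac import _all_lag_mean_vectors, _phase_kernel, pac_cell_from_series, trim_slice
from pacgrid._seeding import rng_for

from _oracles import loop_lagged_length, loop_mean_vector

FS = 600.0


def _tone(freq, duration=20.0, fs=FS, amplitude=1.0, phase=0.0):
    t = np.arange(int(fs * duration)) / fs
    return RegionalTimeSeries(amplitude * np.cos(2 * np.pi * freq * t + phase), fs)


def _interior(n, fs, seconds=2.0):
    return trim_slice(n, fs, seconds)


class TestBandpass:
    def test_passband_preserves_amplitude(self):
        ts = _tone(6.0)
        out = bandpass(ts, (4.0, 8.0))
        mid = out[_interior(ts.n_samples, FS)]
        assert np.abs(mid).max() >= 0.95

    def test_stopband_rejects(self):
        ts = _tone(20.0)
        out = bandpass(ts, (4.0, 8.0))[_interior(int(FS * 20), FS)]
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(0.5)

    def test_mixture_recovers_isolated_component(self):
        t = np.arange(int(FS * 20)) / FS
        mix = RegionalTimeSeries(np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 35 * t), FS)
        pure = RegionalTimeSeries(np.sin(2 * np.pi * 35 * t), FS)
        sl = _interior(mix.n_samples, FS)
        got = bandpass(mix, (30.0, 40.0))[sl]
        want = bandpass(pure, (30.0, 40.0))[sl]
        assert np.sqrt(np.mean((got - want) ** 2)) < 0.05 * np.sqrt(np.mean(want**2))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(PacParameterError):
            bandpass(_tone(6.0, duration=2.0), (100.0, 400.0))


class TestPhaseAndAmplitude:
    def test_cosine_phase_advances_at_carrier_rate(self):
        ts = _tone(6.0)
        sl = _interior(ts.n_samples, FS)
        phase = np.unwrap(phase_series(ts, (4.0, 8.0)))[sl]
        slope = np.polyfit(np.arange(phase.size) / FS, phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.01)

    def test_sine_lags_cosine_by_half_pi(self):
        t = np.arange(int(FS * 20)) / FS
        cos_ts = RegionalTimeSeries(np.cos(2 * np.pi * 6 * t), FS)
        sin_ts = RegionalTimeSeries(np.sin(2 * np.pi * 6 * t), FS)
        sl = _interior(cos_ts.n_samples, FS)
        diff = phase_series(cos_ts, (4.0, 8.0))[sl] - phase_series(sin_ts, (4.0, 8.0))[sl]
        lag = np.angle(np.mean(np.exp(1j * diff)))
        assert lag == pytest.approx(np.pi / 2, abs=0.05)

    def test_noisy_phase_tracks_clean_phase(self, rng):
        t = np.arange(int(FS * 20)) / FS
        clean = np.cos(2 * np.pi * 6 * t)
        noisy = RegionalTimeSeries(clean + 0.3 * rng.standard_normal(t.size), FS)
        sl = _interior(t.size, FS)
        p_clean = phase_series(RegionalTimeSeries(clean, FS), (4.0, 8.0))[sl]
        p_noisy = phase_series(noisy, (4.0, 8.0))[sl]
        coherence = np.abs(np.mean(np.exp(1j * (p_clean - p_noisy))))
        assert coherence > 0.9

    def test_constant_tone_has_constant_envelope(self):
        ts = _tone(35.0, amplitude=2.0)
        env = amplitude_series(ts, (30.0, 40.0))[_interior(ts.n_samples, FS)]
        assert env.mean() == pytest.approx(2.0, rel=0.02)

    def test_am_envelope_tracks_modulator(self):
        t = np.arange(int(FS * 20)) / FS
        modulator = 1 + 0.5 * np.cos(2 * np.pi * 6 * t)
        ts = RegionalTimeSeries(modulator * np.sin(2 * np.pi * 35 * t), FS)
        env = amplitude_series(ts, (25.0, 45.0))[_interior(t.size, FS)]
        r = np.corrcoef(env, modulator[_interior(t.size, FS)])[0, 1]
        assert r > 0.95

    def test_zero_signal_zero_envelope(self):
        ts = RegionalTimeSeries(np.zeros(int(FS * 20)), FS)
        assert np.allclose(amplitude_series(ts, (30.0, 40.0)), 0.0)


class TestSidebandAmplitude:
    def test_sideband_windows_layout(self):
        bands = modulation_sideband_bands((6.0, 7.0), (34.0, 35.0))
        assert bands == ((27.0, 29.0), (34.0, 35.0), (40.0, 42.0))

    def test_phase_band_too_low_for_windows_rejected(self):
        with pytest.raises(PacParameterError):
            modulation_sideband_bands((0.8, 1.2), (34.0, 35.0))

    def test_multiband_matches_time_domain_filter_for_single_band(self, make_coupled):
        """Frequency-domain zero-phase filtering agrees with sosfiltfilt + Hilbert."""
        ts = make_coupled(seed=3)
        sl = _interior(ts.n_samples, FS)
        freq_env = multiband_amplitude_series(ts, ((25.0, 45.0),))[sl]
        time_env = amplitude_series(ts, (25.0, 45.0))[sl]
        err = np.sqrt(np.mean((freq_env - time_env) ** 2)) / np.sqrt(np.mean(time_env**2))
        assert err < 0.01

    def test_overlapping_bands_rejected(self, make_coupled):
        with pytest.raises(PacParameterError):
            multiband_amplitude_series(make_coupled(), ((30.0, 35.0), (34.0, 40.0)))


class TestCompositeAndMeanVector:
    def test_unit_composite(self):
        z = composite_signal(np.ones(4), np.zeros(4))
        np.testing.assert_allclose(z, 1.0 + 0j)

    def test_quarter_turn_composite(self):
        z = composite_signal(2 * np.ones(3), np.full(3, np.pi / 2))
        np.testing.assert_allclose(z, 2j, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(PacParameterError):
            composite_signal(np.ones(3), np.zeros(4))

    def test_cosine_modulated_amplitude_mean_is_half(self):
        """E[(1 + cos(phi)) e^{i phi}] = 1/2 over whole cycles."""
        phi = np.linspace(-np.pi, np.pi, 36_000, endpoint=False)
        m = raw_mean_vector(composite_signal(1 + np.cos(phi), phi))
        assert m.real == pytest.approx(0.5, abs=0.01)
        assert m.imag == pytest.approx(0.0, abs=1e-9)

    def test_uniform_phase_full_cycles_cancels(self):
        phi = np.linspace(-np.pi, np.pi, 6_000, endpoint=False)
        phi = np.tile(phi, 5)
        assert abs(raw_mean_vector(composite_signal(np.ones_like(phi), phi))) < 1e-6

    def test_constant_composite_is_identity(self):
        z = np.full(10, 0.3 - 0.4j)
        assert raw_mean_vector(z) == pytest.approx(0.3 - 0.4j)

    def test_empty_input_rejected(self):
        with pytest.raises(PacParameterError):
            raw_mean_vector(np.array([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mean_vector_length_bounded_by_mean_amplitude(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 200)
        amp = rng.exponential(1.0, n)
        phase = rng.uniform(-np.pi, np.pi, n)
        assert abs(raw_mean_vector(composite_signal(amp, phase))) <= amp.mean() + 1e-12


class TestSurrogates:
    def test_surrogate_count(self, make_coupled):
        ts = make_coupled()
        sl = _interior(ts.n_samples, FS, 1.0)
        amp = amplitude_series(ts, (30.0, 40.0))[sl]
        phase = phase_series(ts, (6.0, 7.0))[sl]
        lengths = surrogate_mvls(amp, phase, FS, n_surrogates=200, rng=rng_for(1))
        assert lengths.shape == (200,)
        assert np.all(lengths >= 0)

    def test_constant_amplitude_gives_degenerate_error(self):
        t = np.arange(int(FS * 20)) / FS
        ts = RegionalTimeSeries(np.sin(2 * np.pi * 34.5 * t), FS)
        with pytest.raises(DegenerateSurrogateError):
            normalized_pac(ts, seeded_band_pair(), n_surrogates=50, rng=rng_for(1))

    def test_coupled_signal_beats_surrogate_tail(self, make_coupled):
        """kappa=1: the observed mean vector exceeds the 99th surrogate percentile."""
        ts = make_coupled(kappa=1.0, seed=6)
        pair = seeded_band_pair()
        sl = _interior(ts.n_samples, FS, 1.0)
        amp = multiband_amplitude_series(
            ts, modulation_sideband_bands(pair.phase_band, pair.amp_band)
        )[sl]
        phase = phase_series(ts, pair.phase_band)[sl]
        observed = abs(raw_mean_vector(composite_signal(amp, phase)))
        lengths = surrogate_mvls(amp, phase, FS, n_surrogates=200, rng=rng_for(2))
        assert observed > np.quantile(lengths, 0.99)

    def test_too_few_surrogates_rejected(self, make_coupled):
        ts = make_coupled()
        with pytest.raises(PacParameterError):
            normalized_pac(ts, seeded_band_pair(), n_surrogates=10, rng=rng_for(1))

    def test_signal_too_short_for_lag_rejected(self):
        rng = rng_for(3)
        amp = rng.random(600)
        phase = rng.uniform(-np.pi, np.pi, 600)
        with pytest.raises(PacParameterError):
            surrogate_mvls(amp, phase, FS, n_surrogates=50, min_lag=1.0, rng=rng)


class TestOracleEquivalence:
    def test_fft_mean_vector_matches_explicit_loop(self, make_coupled):
        """FFT pipeline equals the per-sample loop to 1e-10 on a 5 s fixture."""
        ts = make_coupled(duration=5.0, fs=200.0, f_amp=34.5, seed=7)
        amp = amplitude_series(ts, (30.0, 40.0))
        phase = phase_series(ts, (6.0, 7.0))
        fast = raw_mean_vector(composite_signal(amp, phase))
        slow = loop_mean_vector(amp, phase)
        assert abs(fast - slow) < 1e-10

    def test_all_lag_fft_matches_explicit_lag_loop(self, rng):
        amp = rng.exponential(1.0, 400)
        phase = rng.uniform(-np.pi, np.pi, 400)
        c = _all_lag_mean_vectors(amp, _phase_kernel(np.exp(1j * phase)))
        for lag in (0, 1, 57, 200, 399):
            assert abs(abs(c[lag]) - loop_lagged_length(amp, phase, lag)) < 1e-10


class TestNormalizedPac:
    def test_zscore_definition_holds_exactly(self, make_coupled):
        cell = normalized_pac(
            make_coupled(seed=8), seeded_band_pair(), n_surrogates=50, rng=rng_for(4)
        )
        assert cell.m_norm == pytest.approx((abs(cell.m_raw) - cell.mu) / cell.sigma)
        assert 0 <= cell.phi_norm_deg < 360
        assert cell.sigma > 0

    def test_scale_invariance(self, make_coupled):
        ts = make_coupled(seed=9)
        scaled = RegionalTimeSeries(ts.samples * 137.0, ts.fs)
        pair = seeded_band_pair()
        a = normalized_pac(ts, pair, n_surrogates=50, rng=rng_for(5))
        b = normalized_pac(scaled, pair, n_surrogates=50, rng=rng_for(5))
        assert abs(a.m_norm - b.m_norm) < 1e-6

    def test_null_zscores_include_negative_values(self, make_coupled):
        """M_norm is signed; null signals produce negative values that are kept."""
        vals = [
            normalized_pac(
                make_coupled(kappa=0.0, seed=100 + k),
                seeded_band_pair(),
                n_surrogates=50,
                rng=rng_for(6, k),
            ).m_norm
            for k in range(12)
        ]
        assert min(vals) < 0

    def test_strong_coupling_gives_large_zscore(self, make_coupled):
        cell = normalized_pac(
            make_coupled(kappa=1.0, seed=10), seeded_band_pair(), n_surrogates=50, rng=rng_for(7)
        )
        assert cell.m_norm > 3

    def test_preferred_phase_recovered(self, make_coupled):
        cell = normalized_pac(
            make_coupled(kappa=1.0, preferred_phase=np.pi / 2, seed=11),
            seeded_band_pair(),
            n_surrogates=50,
            rng=rng_for(8),
        )
        err = (cell.phi_norm_deg - 90.0 + 180.0) % 360.0 - 180.0
        assert abs(err) < 15.0

    def test_deterministic_under_fixed_rng(self, make_coupled):
        ts = make_coupled(seed=12)
        a = normalized_pac(ts, seeded_band_pair(), n_surrogates=50, rng=rng_for(9))
        b = normalized_pac(ts, seeded_band_pair(), n_surrogates=50, rng=rng_for(9))
        assert a == b
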