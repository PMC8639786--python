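"""Spectral estimation chain: preprocessing, multitaper CSD, coherence,
power correlation, Wilson factorization, and spectral Granger causality."""

import numpy as np
import pytest

from rhythmnet.containers import CrossSpectra, EpochedRecording
from rhythmnet.spectral import (
    bipolar_derivation,
    coherence_from_csd,
    gc_from_factorization,
    multitaper_csd,
    orthogonalized_power_correlation,
    pairwise_spectral_gc,
    power_correlation,
    remove_line_components,
    taper_fourier_coefficients,
    wilson_factorize,
)
from rhythmnet.synthgen import VarModel, analytic_csd, analytic_var_gc, simulate_var_lfp

from conftest import FS, ar2_coeffs, make_2node_model


def white_recording(n_sites, n_samples, n_epochs, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    return EpochedRecording(
        data=rng.standard_normal((n_sites, n_samples, n_epochs)), fs=fs
    )


class TestBipolarDerivation:
    def test_common_signal_cancels_exactly(self):
        rng = np.random.default_rng(0)
        common = rng.standard_normal((1, 100, 4))
        noise = rng.standard_normal((2, 100, 4))
        raw = EpochedRecording(data=common + noise, fs=FS)
        out = bipolar_derivation(raw, [(0, 1)])
        np.testing.assert_allclose(out.data[0], noise[0] - noise[1], atol=1e-12)

    def test_linear_chain_gives_three_sites(self):
        raw = white_recording(4, 50, 2)
        out = bipolar_derivation(raw, [(0, 1), (1, 2), (2, 3)],
                                 electrode_groups=["lane1"] * 4)
        assert out.n_sites == 3

    def test_cross_group_pair_rejected(self):
        raw = white_recording(4, 50, 2)
        out = bipolar_derivation(
            raw, [(0, 1), (1, 2), (2, 3)],
            electrode_groups=["h1", "h1", "h2", "h2"],
        )
        assert out.n_sites == 2  # (1, 2) spans headstages and is dropped

    def test_midpoint_positions(self):
        raw = white_recording(3, 50, 2)
        pos = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        out = bipolar_derivation(raw, [(0, 1), (1, 2)], electrode_positions=pos)
        np.testing.assert_allclose(out.sites.positions, [[1, 0], [3, 0]])


class TestLineRemoval:
    def test_pure_sinusoid_removed(self):
        t = np.arange(200) / FS
        x = np.sin(2 * np.pi * 50 * t)
        rec = EpochedRecording(
            data=np.broadcast_to(x[None, :, None], (1, 200, 3)).copy(), fs=FS
        )
        out = remove_line_components(rec, [50.0])
        assert np.max(np.abs(out.data)) < 1e-8 * np.max(np.abs(rec.data))

    def test_broadband_psd_untouched_away_from_line(self):
        rec = white_recording(1, 200, 200, seed=1)
        t = np.arange(200) / FS
        noisy = EpochedRecording(
            data=rec.data + 3 * np.sin(2 * np.pi * 50 * t)[None, :, None], fs=FS
        )
        out = remove_line_components(noisy, [50.0])
        psd_ref = np.abs(np.fft.rfft(rec.data, axis=1)) ** 2
        psd_out = np.abs(np.fft.rfft(out.data, axis=1)) ** 2
        freqs = np.fft.rfftfreq(200, 1 / FS)
        away = np.abs(freqs - 50) > 2
        ratio = psd_out[0, away].mean() / psd_ref[0, away].mean()
        assert abs(ratio - 1) < 0.01

    def test_multiple_line_frequencies_suppressed(self):
        t = np.arange(200) / FS
        sig = sum(np.sin(2 * np.pi * f * t + 0.3 * f) for f in (50, 70, 90))
        rec = EpochedRecording(data=sig.reshape(1, 200, 1), fs=FS)
        out = remove_line_components(rec, [50.0, 70.0, 90.0])
        assert np.max(np.abs(out.data)) < 1e-8

    def test_off_bin_frequency_warns(self):
        rec = white_recording(1, 200, 2)
        with pytest.warns(UserWarning, match="nearest bin"):
            remove_line_components(rec, [50.3])

    def test_above_nyquist_rejected(self):
        rec = white_recording(1, 200, 2)
        with pytest.raises(ValueError):
            remove_line_components(rec, [150.0])


class TestMultitaperCSD:
    def test_parseval_white_noise(self):
        rec = white_recording(2, 200, 300, seed=2)
        csd = multitaper_csd(rec, n_tapers=3)
        df = csd.freqs[1] - csd.freqs[0]
        psd_power = np.diagonal(csd.csd, axis1=1, axis2=2).real.sum(axis=0) * df
        var_t = rec.data.var(axis=(1, 2))
        np.testing.assert_allclose(psd_power, var_t, rtol=0.05)

    def test_sinusoid_peak_bin(self):
        t = np.arange(200) / FS
        x = np.sin(2 * np.pi * 10 * t)
        rec = EpochedRecording(
            data=np.broadcast_to(x[None, :, None], (1, 200, 5)).copy(), fs=FS
        )
        csd = multitaper_csd(rec, n_tapers=3)
        assert csd.freqs[np.argmax(csd.csd[:, 0, 0].real)] == 10.0

    def test_identical_channels_cross_equals_auto(self):
        rec = white_recording(1, 200, 20, seed=3)
        dup = EpochedRecording(data=np.vstack([rec.data, rec.data]), fs=FS)
        csd = multitaper_csd(dup, n_tapers=3)
        np.testing.assert_allclose(csd.csd[:, 0, 1], csd.csd[:, 0, 0], atol=1e-12)

    def test_hermitian_invariant(self):
        rec = white_recording(3, 100, 30, seed=4)
        csd = multitaper_csd(rec, n_tapers=2)
        csd.validate_hermitian()

    def test_zero_padding_refines_grid(self):
        rec = white_recording(1, 100, 5, seed=5)  # 0.5 s epochs
        csd = multitaper_csd(rec, n_tapers=3, pad_to_s=1.0)
        assert csd.freqs[1] - csd.freqs[0] == pytest.approx(1.0)


class TestCoherence:
    def test_identical_signals_coherence_one(self):
        rec = white_recording(1, 200, 30, seed=6)
        dup = EpochedRecording(data=np.vstack([rec.data, rec.data]), fs=FS)
        coh = coherence_from_csd(multitaper_csd(dup, 3))
        np.testing.assert_allclose(coh.values[0, 1], 1.0, atol=1e-10)

    def test_independent_channels_bias_small(self):
        rec = white_recording(2, 200, 1000, seed=7)
        coh = coherence_from_csd(multitaper_csd(rec, 3))
        assert coh.values[0, 1].mean() < 0.05

    def test_snr_relation_half_signal(self):
        # y = x + independent noise of equal variance -> coherence ~ 1/sqrt(2)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((1, 200, 800))
        noise = rng.standard_normal((1, 200, 800))
        rec = EpochedRecording(data=np.vstack([x, x + noise]), fs=FS)
        coh = coherence_from_csd(multitaper_csd(rec, 3))
        assert abs(coh.values[0, 1].mean() - 1 / np.sqrt(2)) < 0.03


class TestPowerCorrelation:
    def test_identical_channels_rho_one(self):
        rec = white_recording(1, 100, 40, seed=9)
        dup = EpochedRecording(data=np.vstack([rec.data, rec.data]), fs=FS)
        pc = power_correlation(dup)
        np.testing.assert_allclose(pc.values[0, 1], 1.0, atol=1e-12)

    def test_rank_invariance_under_log(self):
        freqs, coeffs = taper_fourier_coefficients(white_recording(2, 100, 50, seed=10))
        pc_power = power_correlation((freqs, coeffs))
        # log-transforming power leaves Spearman rank correlation unchanged;
        # emulate by exponent-scaling the coefficients' magnitudes per epoch
        power = (np.abs(coeffs) ** 2).mean(axis=1)
        from rhythmnet.spectral import _spearman_pairwise

        rho_raw = _spearman_pairwise(power)
        rho_log = _spearman_pairwise(np.log(power))
        np.testing.assert_allclose(rho_raw, rho_log, atol=1e-12)
        np.testing.assert_allclose(pc_power.values[0, 1], rho_raw[0, 1], atol=1e-12)

    def test_independent_channels_null_level(self):
        rec = white_recording(2, 100, 400, seed=11)
        pc = power_correlation(rec)
        assert np.abs(pc.values[0, 1]).mean() < 2 / np.sqrt(400)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            power_correlation(white_recording(2, 100, 2))


class TestOrthogonalizedPowerCorrelation:
    def test_instantaneous_scaling_rejected(self):
        rec = white_recording(1, 100, 500, seed=12)
        mixed = EpochedRecording(data=np.vstack([rec.data, 2.5 * rec.data]), fs=FS)
        pc = orthogonalized_power_correlation(mixed)
        assert np.abs(pc.values[0, 1]).max() < 0.05

    def test_lagged_envelopes_survive(self):
        # independent fast carriers with a shared slow amplitude envelope and a
        # non-zero phase lag: orthogonalization should preserve the correlation
        rng = np.random.default_rng(13)
        n_ep = 300
        env = 1.0 + 0.8 * np.sin(np.linspace(0, 6 * np.pi, n_ep))
        t = np.arange(100) / FS
        x = np.empty((2, 100, n_ep))
        for e in range(n_ep):
            x[0, :, e] = env[e] * np.sin(2 * np.pi * 20 * t + rng.uniform(0, 2 * np.pi))
            x[1, :, e] = env[e] * np.sin(2 * np.pi * 20 * t + rng.uniform(0, 2 * np.pi))
        rec = EpochedRecording(data=x, fs=FS)
        plain = power_correlation(rec)
        ortho = orthogonalized_power_correlation(rec)
        k = np.argmin(np.abs(plain.freqs - 20))
        # a genuinely phase-lagged shared envelope survives orthogonalization,
        # in contrast to the instantaneous-mixing case above
        assert plain.values[0, 1, k] > 0.9
        assert ortho.values[0, 1, k] > 0.5


class TestWilsonFactorization:
    def test_identity_csd(self):
        S = np.tile(np.eye(2, dtype=complex), (65, 1, 1))
        fact = wilson_factorize(S, tol=1e-12)
        assert fact.converged
        np.testing.assert_allclose(fact.noise_cov, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(fact.transfer,
                                   np.tile(np.eye(2), (65, 1, 1)), atol=1e-8)

    def test_var1_noise_cov_recovery(self, dense_freqs):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.2], [0.0, 0.4]]
        noise = np.array([[1.0, 0.3], [0.3, 2.0]])
        m = VarModel(A, noise, FS)
        S = analytic_csd(m, dense_freqs, onesided_scale=False)
        fact = wilson_factorize(S, tol=1e-13, max_iter=500)
        np.testing.assert_allclose(fact.noise_cov * FS, noise, atol=1e-5)

    def test_reconstruction_residual_within_tol(self, coupled_2node, dense_freqs):
        S = analytic_csd(coupled_2node, dense_freqs)
        fact = wilson_factorize(S, tol=1e-11, max_iter=500)
        assert fact.converged
        assert fact.residual < 1e-8

    def test_non_psd_input_rejected(self):
        S = np.tile(np.diag([1.0, -1.0]).astype(complex), (33, 1, 1))
        with pytest.raises(ValueError, match="positive semi-definite"):
            wilson_factorize(S)


class TestSpectralGC:
    def test_diagonal_csd_gives_zero_gc(self):
        S = np.tile(np.diag([2.0, 3.0]).astype(complex), (65, 1, 1))
        cs = CrossSpectra(freqs=np.linspace(0, FS / 2, 65), csd=S,
                          n_tapers=1, n_epochs=1, smoothing_hz=0)
        gc = pairwise_spectral_gc(cs, tol=1e-12)
        assert np.max(gc.values) < 1e-10

    def test_matches_parametric_oracle(self, coupled_2node, dense_freqs):
        S = analytic_csd(coupled_2node, dense_freqs)
        gt = analytic_var_gc(coupled_2node, dense_freqs)
        cs = CrossSpectra(freqs=dense_freqs, csd=S, n_tapers=1, n_epochs=1,
                          smoothing_hz=0)
        gc = pairwise_spectral_gc(cs, tol=1e-13, max_iter=1000)
        assert np.max(np.abs(gc.values - gt.gc_spectrum)) < 1e-6
        assert np.max(gc.values[1, 0]) < 1e-8  # no influence against coupling

    def test_permutation_equivariance(self, dense_freqs):
        m = make_2node_model(coupling=0.3)
        S = analytic_csd(m, dense_freqs)
        cs = CrossSpectra(freqs=dense_freqs, csd=S, n_tapers=1, n_epochs=1,
                          smoothing_hz=0)
        gc = pairwise_spectral_gc(cs, tol=1e-12, max_iter=500)
        perm = [1, 0]
        Sp = S[:, perm, :][:, :, perm]
        csp = CrossSpectra(freqs=dense_freqs, csd=Sp, n_tapers=1, n_epochs=1,
                           smoothing_hz=0)
        gcp = pairwise_spectral_gc(csp, tol=1e-12, max_iter=500)
        np.testing.assert_allclose(
            gcp.values, gc.values[perm][:, perm], atol=1e-9
        )

    def test_simulated_gc_direction_ratio(self):
        # directed coupling 0 -> 1 only: estimated GC at the oscillator
        # frequency should dominate the reverse direction
        m = make_2node_model(coupling=0.3)
        rec = simulate_var_lfp(None, m, n_epochs=500, epoch_len_s=1.0, seed=21)
        csd = multitaper_csd(rec, 3)
        gc = pairwise_spectral_gc(csd)
        gt = analytic_var_gc(m, csd.freqs)
        kpeak = np.argmax(gt.gc_spectrum[0, 1])
        assert gc.values[0, 1, kpeak] > 5 * gc.values[1, 0, kpeak]
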