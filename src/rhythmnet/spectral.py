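"""Preprocessing and frequency-resolved functional connectivity estimation.

The estimation chain follows standard practice for epoched field-potential
data: local bipolar derivation removes the common recording reference,
line-noise components are subtracted via their DFT amplitudes, cross-spectral
density (CSD) matrices are estimated with Slepian multitapers across
non-overlapping epochs, and three FC metrics are derived: magnitude
coherence, Spearman power correlation across epochs (plain and
orthogonalized), and nonparametric spectral Granger causality (GC). GC is
obtained without autoregressive modeling by factorizing each pair's 2x2 CSD
into a minimum-phase transfer function and innovation covariance with
Wilson's algorithm and applying Geweke's spectral formula.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal.windows import dpss
from scipy.stats import rankdata

from .containers import CrossSpectra, EpochedRecording, FCSpectra, SpectralFactorization
from .synthgen import SiteLayout

logger = logging.getLogger(__name__)

__all__ = [
    "bipolar_derivation",
    "remove_line_components",
    "taper_fourier_coefficients",
    "multitaper_csd",
    "csd_from_coefficients",
    "coherence_from_csd",
    "power_correlation",
    "orthogonalized_power_correlation",
    "wilson_factorize",
    "pairwise_spectral_gc",
    "gc_from_factorization",
]


# ---------------------------------------------------------------------------
# preprocessing

def bipolar_derivation(
    raw_recording: EpochedRecording,
    electrode_adjacency: Sequence[tuple],
    electrode_groups: Optional[Sequence] = None,
    electrode_positions: Optional[np.ndarray] = None,
) -> EpochedRecording:
    """Re-reference by local bipolar derivation (sample-by-sample differences).

    ``electrode_adjacency`` lists neighboring electrode index pairs; each
    admissible pair becomes one derived site. If ``electrode_groups`` is
    given (lane/headstage label per electrode), pairs spanning two groups are
    rejected with a diagnostic, mirroring the rule that derivations are only
    formed within the same grid lane and headstage. Site positions are the
    midpoints of the two electrodes when positions are supplied.
    """
    n_elec = raw_recording.n_sites
    kept, rejected = [], []
    for (a, b) in electrode_adjacency:
        if not (0 <= a < n_elec and 0 <= b < n_elec):
            raise IndexError(f"electrode pair ({a}, {b}) out of range")
        if electrode_groups is not None and electrode_groups[a] != electrode_groups[b]:
            rejected.append((a, b))
            continue
        kept.append((a, b))
    if rejected:
        logger.info("bipolar_derivation: rejected %d pair(s) spanning groups: %s",
                    len(rejected), rejected)
    if not kept:
        raise ValueError("no admissible electrode pairs remain")
    data = np.stack(
        [raw_recording.data[a] - raw_recording.data[b] for (a, b) in kept]
    )
    sites = None
    if electrode_positions is not None:
        pos = np.asarray(electrode_positions, float)
        mid = np.stack([(pos[a] + pos[b]) / 2.0 for (a, b) in kept])
        diff = mid[:, None, :] - mid[None, :, :]
        import pandas as pd

        sites = SiteLayout(
            site_id=[f"bip_{a}_{b}" for (a, b) in kept],
            area=np.asarray(["derived"] * len(kept)),
            subject="derived",
            positions=mid,
            hierarchy_level={"derived": 1.0},
            surface_distance=np.sqrt((diff**2).sum(-1)),
            areas=["derived"],
            area_distance=pd.DataFrame([[0.0]], index=["derived"], columns=["derived"]),
        )
    return EpochedRecording(data=data, fs=raw_recording.fs, sites=sites,
                            condition=raw_recording.condition)


def remove_line_components(
    recording: EpochedRecording, line_freqs: Sequence[float]
) -> EpochedRecording:
    """Estimate and subtract sinusoidal line components per epoch and site.

    For each listed frequency the complex DFT amplitude is estimated on each
    epoch and the corresponding sinusoid subtracted, zeroing the power at
    that bin. Frequencies that do not fall on a DFT bin of the epoch length
    trigger a warning and are snapped to the nearest bin.
    """
    fs = recording.fs
    N = recording.n_samples
    data = recording.data.copy()
    X = np.fft.rfft(data, axis=1)
    nbins = X.shape[1]
    for f in line_freqs:
        if f >= fs / 2.0 or f < 0:
            raise ValueError(f"line frequency {f} Hz not below Nyquist ({fs / 2} Hz)")
        k = f * N / fs
        kr = int(round(k))
        if abs(k - kr) > 1e-9:
            warnings.warn(
                f"line frequency {f} Hz not resolvable at epoch length "
                f"{N / fs} s; using nearest bin {kr * fs / N} Hz"
            )
        kr = min(kr, nbins - 1)
        X[:, kr, :] = 0.0
    cleaned = np.fft.irfft(X, n=N, axis=1)
    return EpochedRecording(data=cleaned, fs=fs, sites=recording.sites,
                            condition=recording.condition)


# ---------------------------------------------------------------------------
# multitaper spectral estimation

def taper_fourier_coefficients(
    recording: EpochedRecording,
    n_tapers: int = 3,
    pad_to_s: Optional[float] = None,
):
    """Slepian-tapered Fourier coefficients of every epoch.

    Epochs are multiplied by ``n_tapers`` unit-energy DPSS tapers
    (time-bandwidth NW = (n_tapers + 1) / 2) and Fourier transformed, with
    optional zero-padding to ``pad_to_s`` seconds to interpolate the
    frequency grid (grid step ``1 / pad_to_s``). The coefficients carry a
    ``sqrt(2 / fs)`` scaling so products directly yield one-sided spectral
    densities.

    Returns ``(freqs, coeffs)`` with ``coeffs`` of shape
    ``(n_epochs, n_tapers, n_sites, n_freq)``.
    """
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    fs, N = recording.fs, recording.n_samples
    if pad_to_s is None:
        nfft = N
    else:
        if pad_to_s < recording.epoch_len:
            raise ValueError("pad_to_s must be >= epoch length")
        nfft = int(round(pad_to_s * fs))
    nw = (n_tapers + 1) / 2.0
    tapers = dpss(N, nw, Kmax=n_tapers)  # (n_tapers, N), unit energy
    # (sites, N, epochs) -> (epochs, tapers, sites, N)
    x = np.transpose(recording.data, (2, 0, 1))[:, None, :, :] * tapers[None, :, None, :]
    coeffs = np.fft.rfft(x, n=nfft, axis=-1) * np.sqrt(2.0 / fs)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, coeffs


def csd_from_coefficients(coeffs: np.ndarray) -> np.ndarray:
    """Average tapered coefficients into CSD matrices, shape (n_freq, n, n)."""
    n_epochs, n_tapers = coeffs.shape[0], coeffs.shape[1]
    S = np.einsum("etsf,etuf->fsu", coeffs, np.conj(coeffs))
    return S / (n_epochs * n_tapers)


def multitaper_csd(
    recording: EpochedRecording,
    n_tapers: int = 3,
    pad_to_s: Optional[float] = None,
) -> CrossSpectra:
    """Multitaper cross-spectral density averaged over tapers and epochs."""
    freqs, coeffs = taper_fourier_coefficients(recording, n_tapers, pad_to_s)
    S = csd_from_coefficients(coeffs)
    T = recording.epoch_len
    return CrossSpectra(
        freqs=freqs,
        csd=S,
        n_tapers=n_tapers,
        n_epochs=recording.n_epochs,
        smoothing_hz=(n_tapers + 1) / 2.0 / T,
    )


# ---------------------------------------------------------------------------
# undirected FC metrics

def coherence_from_csd(csd: CrossSpectra) -> FCSpectra:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy), in [0, 1]."""
    S = csd.csd
    auto = np.diagonal(S, axis1=1, axis2=2).real  # (n_freq, n)
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(S) / denom
    coh[denom == 0] = np.nan  # undefined where an auto-spectrum vanishes
    values = np.transpose(np.clip(coh, 0.0, 1.0), (1, 2, 0))
    return FCSpectra(fc_type="coherence", freqs=csd.freqs, values=values,
                     n_epochs=csd.n_epochs)


def _spearman_pairwise(power: np.ndarray) -> np.ndarray:
    """Spearman correlation across axis 0 for every site pair and frequency.

    ``power``: (n_epochs, n_sites, n_freq). Returns (n_sites, n_sites, n_freq);
    zero-variance series yield 0 (degenerate, by convention).
    """
    n_epochs = power.shape[0]
    ranks = rankdata(power, axis=0)
    z = ranks - ranks.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, keepdims=True)
    degenerate = sd[0] == 0  # (n_sites, n_freq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, z / sd, 0.0)
    rho = np.einsum("esf,euf->suf", z, z) / n_epochs
    bad = degenerate[:, None, :] | degenerate[None, :, :]
    rho[bad] = 0.0
    return np.clip(rho, -1.0, 1.0)


def power_correlation(
    source: Union[EpochedRecording, tuple],
    n_tapers: int = 3,
    pad_to_s: Optional[float] = None,
) -> FCSpectra:
    """Spearman rank correlation of single-epoch power across epochs.

    Power is the taper-averaged squared Fourier magnitude of each
    non-overlapping epoch; the correlation is computed per frequency bin
    across epochs and is symmetric in site order. ``source`` is either an
    :class:`EpochedRecording` or a precomputed ``(freqs, coeffs)`` pair from
    :func:`taper_fourier_coefficients`. Zero-variance (constant) power series
    are flagged by a 0 value (degenerate).
    """
    if isinstance(source, EpochedRecording):
        freqs, coeffs = taper_fourier_coefficients(source, n_tapers, pad_to_s)
    else:
        freqs, coeffs = source
    if coeffs.shape[0] < 3:
        raise ValueError("power correlation requires at least 3 epochs")
    power = (np.abs(coeffs) ** 2).mean(axis=1)  # (n_epochs, n_sites, n_freq)
    rho = _spearman_pairwise(power)
    for i in range(rho.shape[0]):
        rho[i, i] = 1.0
    return FCSpectra(fc_type="powcorr", freqs=freqs, values=rho,
                     n_epochs=coeffs.shape[0])


def orthogonalized_power_correlation(
    source: Union[EpochedRecording, tuple],
    n_tapers: int = 3,
    pad_to_s: Optional[float] = None,
) -> FCSpectra:
    """Power correlation after per-epoch orthogonalization of the coefficients.

    Before computing power, each site's tapered Fourier coefficient is
    orthogonalized against the partner site's coefficient (keeping only the
    component with a 90-degree phase relation), which removes zero-lag
    (instantaneously mixed) contributions on an epoch-by-epoch basis. The two
    orthogonalization directions are averaged. Identical (or purely scaled)
    signals are fully removed and yield 0, flagged as degenerate.
    """
    if isinstance(source, EpochedRecording):
        freqs, coeffs = taper_fourier_coefficients(source, n_tapers, pad_to_s)
    else:
        freqs, coeffs = source
    n_epochs, n_tapers_, n_sites, n_freq = coeffs.shape
    if n_epochs < 3:
        raise ValueError("power correlation requires at least 3 epochs")
    absX = np.abs(coeffs)
    power = (absX**2).mean(axis=1)  # plain power, (n_epochs, n_sites, n_freq)
    values = np.zeros((n_sites, n_sites, n_freq))
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            Xi, Xj = coeffs[:, :, i, :], coeffs[:, :, j, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                # component of j orthogonal to i, and vice versa
                pj_orth = (np.imag(Xj * np.conj(Xi) / np.where(absX[:, :, i, :] > 0,
                           absX[:, :, i, :], 1.0)) ** 2).mean(axis=1)
                pi_orth = (np.imag(Xi * np.conj(Xj) / np.where(absX[:, :, j, :] > 0,
                           absX[:, :, j, :], 1.0)) ** 2).mean(axis=1)
            # orthogonalized power that is pure rounding noise (signals are
            # identical up to real scaling) counts as fully removed
            degen_j = pj_orth.mean(0) < 1e-12 * power[:, j, :].mean(0)
            degen_i = pi_orth.mean(0) < 1e-12 * power[:, i, :].mean(0)
            r1 = _spearman_pairwise(
                np.stack([power[:, i, :], pj_orth], axis=1))[0, 1]
            r2 = _spearman_pairwise(
                np.stack([power[:, j, :], pi_orth], axis=1))[0, 1]
            r1 = np.where(degen_j, 0.0, r1)
            r2 = np.where(degen_i, 0.0, r2)
            values[i, j] = values[j, i] = 0.5 * (r1 + r2)
    return FCSpectra(fc_type="powcorr_ortho", freqs=freqs, values=values,
                     n_epochs=n_epochs)


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization and Granger causality

def _plus_operator(g: np.ndarray, m_onesided: int) -> np.ndarray:
    """Causal (non-negative lag) part of a spectral matrix function.

    ``g``: (N2, n, n) on the full two-sided grid. The zero lag is split
    between the causal and anticausal parts: its diagonal is halved and only
    the upper triangle kept, matching the upper-triangular initialization of
    the factor.
    """
    gam = np.fft.ifft(g, axis=0).real
    gam[0] = np.triu(0.5 * gam[0])
    gam[m_onesided - 1:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    csd: Union[CrossSpectra, np.ndarray],
    tol: float = 1e-9,
    max_iter: int = 100,
    check_psd: bool = True,
) -> SpectralFactorization:
    """Wilson's iterative spectral matrix factorization S(f) = H Sigma H*.

    Operates on a Hermitian CSD sampled on a uniform grid from 0 to the
    Nyquist frequency and returns the minimum-phase transfer function ``H``
    and innovation covariance ``Sigma``. Iteration stops when the relative
    update of the factor falls below ``tol``; if ``max_iter`` is reached the
    result is returned with ``converged=False``. The reported ``residual`` is
    the relative Frobenius reconstruction error of ``H Sigma H*`` against the
    input.
    """
    if isinstance(csd, CrossSpectra):
        S1, freqs = csd.csd, csd.freqs
    else:
        S1 = np.asarray(csd, dtype=complex)
        freqs = np.arange(S1.shape[0], dtype=float)
    M, n = S1.shape[0], S1.shape[1]
    if check_psd:
        w = np.linalg.eigvalsh((S1 + np.conj(np.transpose(S1, (0, 2, 1)))) / 2.0)
        scale = max(float(np.max(np.abs(S1))), 1e-300)
        bad = np.flatnonzero(w.min(axis=1) < -1e-8 * scale)
        if bad.size:
            raise ValueError(
                f"CSD not positive semi-definite at frequency {freqs[bad[0]]:g}"
            )
    N2 = 2 * (M - 1)
    Sfull = np.empty((N2, n, n), dtype=complex)
    Sfull[:M] = S1
    Sfull[M:] = np.conj(S1[M - 2:0:-1])

    # init: upper Cholesky factor of the lag-0 covariance
    C = Sfull.mean(axis=0).real
    C = (C + C.T) / 2.0
    jitter = 1e-12 * max(np.trace(C) / n, 1e-300)
    h = np.linalg.cholesky(C + jitter * np.eye(n)).conj().T
    psi = np.tile(h.astype(complex), (N2, 1, 1))
    eye = np.eye(n)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + eye
        gp = _plus_operator(g, M)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break

    A0 = np.fft.ifft(psi, axis=0).real[0]
    Sigma = A0 @ A0.T
    H = psi[:M] @ np.linalg.inv(A0)
    recon = H @ Sigma @ np.conj(np.transpose(H, (0, 2, 1)))
    residual = float(
        np.linalg.norm(recon - S1) / max(np.linalg.norm(S1), 1e-300)
    )
    return SpectralFactorization(
        freqs=freqs, transfer=H, noise_cov=Sigma,
        converged=converged, iterations=it, residual=residual,
    )


def gc_from_factorization(
    fact: SpectralFactorization, S: np.ndarray
) -> np.ndarray:
    """Geweke spectral GC for both directions of a 2-channel factorization.

    GC from y to x: ``ln(S_xx / (S_xx - (Sigma_yy - Sigma_xy^2 / Sigma_xx)
    |H_xy|^2))``. Returns (2, 2, n_freq) with [i, j] = GC i -> j; negative
    numerical values are clipped at zero.
    """
    H, Sigma = fact.transfer, fact.noise_cov
    nf = H.shape[0]
    out = np.zeros((2, 2, nf))
    Sxx, Syy = S[:, 0, 0].real, S[:, 1, 1].real
    s_y_cond = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]
    s_x_cond = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1, 0] = np.log(Sxx / (Sxx - s_y_cond * np.abs(H[:, 0, 1]) ** 2))
        out[0, 1] = np.log(Syy / (Syy - s_x_cond * np.abs(H[:, 1, 0]) ** 2))
    out[~np.isfinite(out)] = 0.0
    return np.clip(out, 0.0, None)


def pairwise_spectral_gc(
    csd: CrossSpectra,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> FCSpectra:
    """Nonparametric spectral GC for both directions of every site pair.

    Each pair's 2x2 sub-CSD is factorized with :func:`wilson_factorize`
    (bivariate GC); pairs whose factorization fails are masked and logged,
    and the remaining pairs are still returned.
    """
    S = csd.csd
    n = csd.n_sites
    if n < 2:
        raise ValueError("GC requires at least 2 sites")
    nf = S.shape[0]
    values = np.zeros((n, n, nf))
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    for i in range(n):
        for j in range(i + 1, n):
            sub = S[:, [i, j], :][:, :, [i, j]]
            try:
                fact = wilson_factorize(sub, tol=tol, max_iter=max_iter,
                                        check_psd=False)
                gc = gc_from_factorization(fact, sub)
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("GC factorization failed for pair (%d, %d): %s",
                               i, j, exc)
                mask[i, j] = mask[j, i] = False
                continue
            values[i, j] = gc[0, 1]
            values[j, i] = gc[1, 0]
    return FCSpectra(fc_type="gc", freqs=csd.freqs, values=values,
                     n_epochs=csd.n_epochs, mask=mask)
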