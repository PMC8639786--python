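"""Synthetic recordings and tracer anatomy with known ground truth.

Two generators are provided. The signal generator realizes band-limited
oscillatory field potentials as stable vector-autoregressive (VAR) processes:
each site is an AR(2) oscillator with poles at a chosen rhythm frequency, and
directed lagged coupling between sites decays exponentially with inter-site
distance, mimicking the distance dependence observed in cortical functional
connectivity. Because the generating model is a VAR, its cross-spectral
density, coherence, and Geweke spectral Granger causality have closed forms
(:func:`analytic_var_gc`), which serve as exact oracles for the nonparametric
spectral estimators.

The anatomy generator emulates a retrograde-tracer database: projection
weights follow an exponential distance rule (EDR) with lognormal scatter,
labeled-neuron counts are drawn multinomially per injected target area, and
the supragranular fraction of each projection follows a logistic function of
the hierarchy-level difference between target and source, so that
feedforward projections (low to high) have SLN > 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EpochedRecording

__all__ = [
    "SiteLayout",
    "VarModel",
    "GroundTruthFC",
    "AnatomyGenConfig",
    "generate_site_layout",
    "band_coupled_var_model",
    "simulate_var_lfp",
    "analytic_csd",
    "analytic_var_gc",
    "generate_anatomy",
]


@dataclass
class SiteLayout:
    """Planar layout of recording sites grouped into contiguous area patches."""

    site_id: list
    area: np.ndarray  # area label per site
    subject: str
    positions: np.ndarray  # (n_sites, 2), mm
    hierarchy_level: dict  # area -> level (strictly ordered across areas)
    surface_distance: np.ndarray  # (n_sites, n_sites), mm
    areas: list = field(default_factory=list)  # unique areas, hierarchy order
    area_distance: Optional[pd.DataFrame] = None  # area x area centroid distance, mm

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def site_indices(self, area: str) -> np.ndarray:
        return np.flatnonzero(self.area == area)


@dataclass
class VarModel:
    """Stable VAR(p) model: x[t] = sum_k A_k x[t-k] + eps, eps ~ N(0, Sigma)."""

    coeffs: np.ndarray  # (order, n, n); coeffs[k][j, i] couples site i -> site j at lag k+1
    noise_cov: np.ndarray  # (n, n) SPD
    sampling_rate: float
    oscillator_freqs: Optional[np.ndarray] = None  # Hz per site

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValueError("coeffs must be (order, n, n)")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive definite")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        """Spectral radius of the VAR companion matrix (< 1 means stable)."""
        p, n = self.order, self.n_sites
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def require_stable(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR model: companion spectral radius {rho:.4f} >= 1"
            )


@dataclass
class GroundTruthFC:
    """Analytic (non-sampled) spectra of a VAR model."""

    freqs: np.ndarray
    gc_spectrum: np.ndarray  # (n, n, n_freq); [i, j] = GC i -> j
    coherence_spectrum: np.ndarray  # (n, n, n_freq) in [0, 1]


@dataclass
class AnatomyGenConfig:
    """Parameters of the synthetic tracer-anatomy generator.

    ``lambda_decay`` is the EDR decay rate in 1/mm (default matches the decay
    rate reported for macaque white-matter distances), ``lognormal_sigma`` the
    standard deviation of the lognormal weight scatter, and ``sln_slope`` the
    logistic slope of the supragranular fraction per hierarchy-level unit.
    """

    lambda_decay: float = 0.202
    lognormal_sigma: float = 1.0
    total_neurons_per_injection: int = 100_000
    sln_slope: float = 1.5
    seed: int = 0
    sample_counts: bool = True  # False: expected (real-valued) counts, noise-free

    def __post_init__(self):
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be >= 0")
        if self.total_neurons_per_injection <= 0:
            raise ValueError("total_neurons_per_injection must be > 0")


def generate_site_layout(
    n_areas: int,
    sites_per_area: int,
    spacing_mm: float = 2.0,
    seed: int = 0,
    subject: str = "subject1",
) -> SiteLayout:
    """Lay out ``n_areas`` contiguous area patches of sites on a planar sheet.

    Sites within an area form a compact grid with pitch ``spacing_mm``; area
    patches are juxtaposed along one axis so the full sheet is contiguous.
    Hierarchy levels are 1..n_areas in patch order. The construction is fully
    deterministic; ``seed`` is accepted for interface uniformity with the
    other generators.
    """
    if n_areas < 2:
        raise ValueError("n_areas must be >= 2")
    if sites_per_area < 1:
        raise ValueError("sites_per_area must be >= 1")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")

    rows = int(math.ceil(math.sqrt(sites_per_area)))
    cols = int(math.ceil(sites_per_area / rows))
    areas = [f"A{a + 1:02d}" for a in range(n_areas)]
    site_id, area_of_site, pos = [], [], []
    for a, name in enumerate(areas):
        x0 = a * cols * spacing_mm
        for k in range(sites_per_area):
            c, r = divmod(k, rows)
            site_id.append(f"{name}_s{k + 1:02d}")
            area_of_site.append(name)
            pos.append((x0 + c * spacing_mm, r * spacing_mm))
    positions = np.asarray(pos, dtype=float)
    diff = positions[:, None, :] - positions[None, :, :]
    surface = np.sqrt((diff**2).sum(-1))

    centroids = np.stack(
        [positions[np.asarray(area_of_site) == nm].mean(axis=0) for nm in areas]
    )
    cdiff = centroids[:, None, :] - centroids[None, :, :]
    area_dist = pd.DataFrame(
        np.sqrt((cdiff**2).sum(-1)), index=areas, columns=areas
    )
    levels = {nm: float(a + 1) for a, nm in enumerate(areas)}
    return SiteLayout(
        site_id=site_id,
        area=np.asarray(area_of_site),
        subject=subject,
        positions=positions,
        hierarchy_level=levels,
        surface_distance=surface,
        areas=areas,
        area_distance=area_dist,
    )


def _ar2_coeffs(freq_hz: float, radius: float, fs: float) -> tuple:
    """AR(2) coefficients with complex pole pair at ``freq_hz`` and the given radius."""
    theta = 2.0 * np.pi * freq_hz / fs
    return 2.0 * radius * np.cos(theta), -(radius**2)


def band_coupled_var_model(
    layout: SiteLayout,
    oscillator_freqs: Sequence[float],
    fs: float = 200.0,
    pole_radius: float = 0.95,
    coupling_strength: float = 0.2,
    decay_per_mm: float = 0.04,
    coupling_lag: int = 3,
    coupling_pairs: Optional[Sequence[tuple]] = None,
    noise_var: float = 1.0,
) -> VarModel:
    """Build a VAR model of AR(2) oscillators with distance-decaying directed coupling.

    Each site ``i`` resonates at ``oscillator_freqs[i]`` (poles at radius
    ``pole_radius``). Directed coupling from site ``i`` to ``j`` enters at lag
    ``coupling_lag`` with magnitude ``coupling_strength * exp(-decay_per_mm *
    d_ij)``; restrict it to ``coupling_pairs`` (ordered ``(i, j)`` tuples) to
    plant a known directed graph. Raises if the resulting model is unstable.
    """
    n = layout.n_sites
    freqs = np.broadcast_to(np.asarray(oscillator_freqs, float), (n,))
    order = max(2, coupling_lag)
    A = np.zeros((order, n, n))
    for i in range(n):
        a1, a2 = _ar2_coeffs(freqs[i], pole_radius, fs)
        A[0, i, i] = a1
        A[1, i, i] = a2
    if coupling_pairs is None:
        coupling_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    # normalize incoming coupling by in-degree so total drive per site (and
    # hence stability) is roughly independent of network size
    indeg = np.zeros(n)
    for (_, j) in coupling_pairs:
        indeg[j] += 1
    for (i, j) in coupling_pairs:
        d = layout.surface_distance[i, j]
        A[coupling_lag - 1, j, i] += (
            coupling_strength * np.exp(-decay_per_mm * d) / max(indeg[j], 1.0)
        )
    model = VarModel(
        coeffs=A,
        noise_cov=noise_var * np.eye(n),
        sampling_rate=fs,
        oscillator_freqs=np.array(freqs),
    )
    model.require_stable()
    return model


def simulate_var_lfp(
    layout: Optional[SiteLayout],
    var_model: VarModel,
    n_epochs: int,
    epoch_len_s: float,
    mixing_matrix: Optional[np.ndarray] = None,
    seed: int = 0,
    burn_in: int = 500,
    condition: Optional[str] = None,
) -> EpochedRecording:
    """Simulate independent epochs of the VAR model.

    Each epoch is an independent realization (separate burn-in), matching the
    treatment of non-overlapping data epochs as independent samples in the
    spectral estimators. ``mixing_matrix`` applies an instantaneous linear
    mixing to the outputs (a volume-conduction surrogate).
    """
    var_model.require_stable()
    fs = var_model.sampling_rate
    n_samples = epoch_len_s * fs
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError("epoch_len_s * sampling_rate must be an integer")
    n_samples = int(round(n_samples))
    n, p = var_model.n_sites, var_model.order
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(var_model.noise_cov)
    total = burn_in + n_samples
    # state x: (n, n_epochs); simulate all epochs in parallel
    eps = rng.standard_normal((total, n, n_epochs))
    eps = np.einsum("ij,tjk->tik", L, eps)
    hist = np.zeros((p, n, n_epochs))
    out = np.empty((n_samples, n, n_epochs))
    A = var_model.coeffs
    for t in range(total):
        x = eps[t]
        for k in range(p):
            x = x + A[k] @ hist[k]
        if p > 0:
            hist = np.roll(hist, 1, axis=0)
            hist[0] = x
        if t >= burn_in:
            out[t - burn_in] = x
    data = np.transpose(out, (1, 0, 2))  # (n_sites, n_samples, n_epochs)
    if mixing_matrix is not None:
        mixing_matrix = np.asarray(mixing_matrix, float)
        data = np.einsum("ij,jte->ite", mixing_matrix, data)
    cond = None if condition is None else np.asarray([condition] * n_epochs)
    return EpochedRecording(data=data, fs=fs, sites=layout, condition=cond)


def analytic_csd(
    var_model: VarModel, freqs: np.ndarray, onesided_scale: bool = True
) -> np.ndarray:
    """Exact cross-spectral density of the VAR model on the given frequency grid.

    Returns ``(n_freq, n, n)`` complex. With ``onesided_scale`` the density
    carries the uniform ``2/fs`` one-sided convention used by
    :class:`rhythmnet.containers.CrossSpectra`.
    """
    var_model.require_stable()
    freqs = np.asarray(freqs, float)
    fs = var_model.sampling_rate
    n, p = var_model.n_sites, var_model.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    Af = np.tile(np.eye(n, dtype=complex), (freqs.size, 1, 1))
    for k in range(p):
        Af -= z[:, k][:, None, None] * var_model.coeffs[k]
    dets = np.linalg.det(Af)
    bad = np.abs(dets) < 1e-300
    if bad.any():
        raise FloatingPointError(
            f"transfer matrix singular at frequency {freqs[bad][0]:g} Hz"
        )
    H = np.linalg.inv(Af)
    S = H @ var_model.noise_cov @ np.conj(np.transpose(H, (0, 2, 1)))
    scale = (2.0 / fs) if onesided_scale else (1.0 / fs)
    return S * scale


def _pairwise_geweke(H: np.ndarray, Sigma: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Geweke spectral GC for both directions of a 2-channel factorization.

    ``H``: (n_freq, 2, 2), ``Sigma``: (2, 2), ``S``: (n_freq, 2, 2).
    Returns (2, 2, n_freq) with [i, j] = GC i -> j and zero diagonal.
    """
    nf = H.shape[0]
    out = np.zeros((2, 2, nf))
    Sxx = S[:, 0, 0].real
    Syy = S[:, 1, 1].real
    # y -> x (1 -> 0)
    s_y_cond = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]
    intrinsic = Sxx - s_y_cond * np.abs(H[:, 0, 1]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1, 0] = np.log(Sxx / intrinsic)
    # x -> y (0 -> 1)
    s_x_cond = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    intrinsic = Syy - s_x_cond * np.abs(H[:, 1, 0]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out[0, 1] = np.log(Syy / intrinsic)
    out[~np.isfinite(out)] = 0.0
    return np.clip(out, 0.0, None)


def analytic_var_gc(var_model: VarModel, freqs: np.ndarray) -> GroundTruthFC:
    """Exact coherence and pairwise Geweke GC spectra of a VAR model.

    The transfer function ``H(f) = (I - sum_k A_k e^(-2*pi*i*f*k/fs))^-1``
    and noise covariance give the exact spectral matrix ``S = H Sigma H*``;
    GC for an ordered pair is evaluated from the corresponding 2x2 blocks of
    ``H`` and ``Sigma``, which is exact for 2-site models and for any pair
    that is dynamically closed (e.g. block-diagonal models). GC of decoupled
    channels is identically zero.
    """
    freqs = np.asarray(freqs, float)
    fs = var_model.sampling_rate
    n, p = var_model.n_sites, var_model.order
    z = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)
    Af = np.tile(np.eye(n, dtype=complex), (freqs.size, 1, 1))
    for k in range(p):
        Af -= z[:, k][:, None, None] * var_model.coeffs[k]
    H = np.linalg.inv(Af)
    Sigma = var_model.noise_cov
    S = H @ Sigma @ np.conj(np.transpose(H, (0, 2, 1)))

    diag = np.sqrt(np.abs(np.diagonal(S, axis1=1, axis2=2).real))
    coh = np.abs(S) / (diag[:, :, None] * diag[:, None, :] + 1e-300)
    coh = np.transpose(np.clip(coh, 0.0, 1.0), (1, 2, 0))

    gc = np.zeros((n, n, freqs.size))
    for i in range(n):
        for j in range(i + 1, n):
            idx = np.ix_([i, j], [i, j])
            sub = _pairwise_geweke(H[:, :, :][:, [i, j], :][:, :, [i, j]],
                                   Sigma[idx], S[:, [i, j], :][:, :, [i, j]])
            gc[i, j] = sub[0, 1]
            gc[j, i] = sub[1, 0]
    return GroundTruthFC(freqs=freqs, gc_spectrum=gc, coherence_spectrum=coh)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_anatomy(layout: SiteLayout, config: AnatomyGenConfig) -> pd.DataFrame:
    """Generate a synthetic directed tracer-anatomy table for the layout's areas.

    For every ordered area pair (source -> target): the expected projection
    weight is ``exp(-lambda * d) * exp(sigma * z)`` with standard-normal
    ``z``; labeled-neuron counts are drawn from one multinomial per injected
    target (total ``total_neurons_per_injection``), so FLNe sums to exactly 1
    over the extrinsic sources of each target; supragranular counts are
    binomial with success probability ``logistic(sln_slope * (level_target -
    level_source))``, making projections up the hierarchy feedforward-like
    (SLN > 0.5). With ``sample_counts=False`` counts are their expected
    (real-valued) values, giving a noise-free table for parameter-recovery
    checks.

    Returns a tidy table with columns ``source, target, n_labeled, n_supra,
    n_infra, flne, sln, dist_wm_mm, dist_surface_mm``.
    """
    if layout.n_areas < 2:
        raise ValueError("layout must contain at least 2 areas")
    rng = np.random.default_rng(config.seed)
    areas = layout.areas
    dist = layout.area_distance.to_numpy()
    rows = []
    for t, target in enumerate(areas):
        sources = [s for s in range(len(areas)) if s != t]
        d = dist[sources, t]
        scatter = (
            rng.standard_normal(len(sources)) * config.lognormal_sigma
            if config.lognormal_sigma > 0
            else np.zeros(len(sources))
        )
        w = np.exp(-config.lambda_decay * d + scatter)
        p = w / w.sum()
        total = config.total_neurons_per_injection
        if config.sample_counts:
            counts = rng.multinomial(total, p).astype(float)
        else:
            counts = total * p
        lvl_t = layout.hierarchy_level[target]
        for k, s in enumerate(sources):
            lvl_s = layout.hierarchy_level[areas[s]]
            p_supra = _logistic(config.sln_slope * (lvl_t - lvl_s))
            n_lab = counts[k]
            if config.sample_counts:
                n_sup = float(rng.binomial(int(n_lab), p_supra)) if n_lab > 0 else 0.0
            else:
                n_sup = n_lab * p_supra
            rows.append(
                {
                    "source": areas[s],
                    "target": target,
                    "n_labeled": n_lab,
                    "n_supra": n_sup,
                    "n_infra": n_lab - n_sup,
                    "flne": n_lab / total,
                    "sln": (n_sup / n_lab) if n_lab > 0 else np.nan,
                    "dist_wm_mm": d[k],
                    "dist_surface_mm": d[k],
                }
            )
    return pd.DataFrame(rows)
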