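"""Shared fixtures: small layouts and 2-node VAR models with known spectra."""

import numpy as np
import pytest

from rhythmnet.synthgen import SiteLayout, VarModel, generate_site_layout

FS = 200.0


def ar2_coeffs(freq_hz: float, radius: float, fs: float = FS):
    theta = 2 * np.pi * freq_hz / fs
    return 2 * radius * np.cos(theta), -(radius**2)


def make_2node_model(
    f1=20.0, f2=40.0, radius=0.9, coupling=0.25, lag=3, sigma_xy=0.2, fs=FS
) -> VarModel:
    """Two AR(2) oscillators with unidirectional coupling 0 -> 1 at the given lag."""
    order = max(2, lag)
    A = np.zeros((order, 2, 2))
    a1, a2 = ar2_coeffs(f1, radius, fs)
    A[0, 0, 0], A[1, 0, 0] = a1, a2
    b1, b2 = ar2_coeffs(f2, radius, fs)
    A[0, 1, 1], A[1, 1, 1] = b1, b2
    A[lag - 1, 1, 0] = coupling
    noise = np.array([[1.0, sigma_xy], [sigma_xy, 1.5]])
    return VarModel(coeffs=A, noise_cov=noise, sampling_rate=fs)


@pytest.fixture
def small_layout() -> SiteLayout:
    return generate_site_layout(n_areas=4, sites_per_area=2, spacing_mm=2.0, seed=7)


@pytest.fixture
def coupled_2node() -> VarModel:
    return make_2node_model()


@pytest.fixture
def dense_freqs() -> np.ndarray:
    return np.linspace(0.0, FS / 2, 513)
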