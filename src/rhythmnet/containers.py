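"""Shared in-memory containers for the spectral analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class EpochedRecording:
    """Epoched multichannel field-potential recording.

    Parameters
    ----------
    data : ndarray, shape (n_sites, n_samples, n_epochs)
        Real-valued signals; epochs are treated as independent realizations.
    fs : float
        Sampling rate in Hz.
    sites : object, optional
        Site layout (see :class:`rhythmnet.synthgen.SiteLayout`).
    condition : ndarray of str, optional
        One condition label per epoch.
    """

    data: np.ndarray
    fs: float
    sites: Optional[object] = None
    condition: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_sites, n_samples, n_epochs), got shape {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN samples")
        if self.condition is not None:
            self.condition = np.asarray(self.condition)
            if self.condition.shape[0] != self.n_epochs:
                raise ValueError("condition must have one label per epoch")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_len(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    def select_condition(self, label: str) -> "EpochedRecording":
        """Return the sub-recording with epochs matching ``label``."""
        if self.condition is None:
            raise ValueError("recording carries no condition labels")
        keep = self.condition == label
        if not keep.any():
            raise ValueError(f"no epochs with condition {label!r}")
        return EpochedRecording(
            self.data[:, :, keep], self.fs, sites=self.sites,
            condition=self.condition[keep],
        )


@dataclass
class CrossSpectra:
    """Frequency-resolved cross-spectral density matrices.

    ``csd[f]`` is the Hermitian one-sided cross-spectral density matrix at
    ``freqs[f]``; a uniform ``2/fs`` scaling is applied at every bin
    (including DC and Nyquist) so that factorization-based statistics see a
    consistent density across the grid.
    """

    freqs: np.ndarray
    csd: np.ndarray  # (n_freq, n_sites, n_sites) complex
    n_tapers: int
    n_epochs: int
    smoothing_hz: float

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.ndim != 3 or self.csd.shape[1] != self.csd.shape[2]:
            raise ValueError("csd must be (n_freq, n_sites, n_sites)")
        if self.csd.shape[0] != self.freqs.size:
            raise ValueError("csd and freqs disagree on the number of bins")

    @property
    def n_sites(self) -> int:
        return self.csd.shape[1]

    def validate_hermitian(self, tol: float = 1e-10) -> None:
        herm = np.max(np.abs(self.csd - np.conj(np.transpose(self.csd, (0, 2, 1)))))
        scale = max(np.max(np.abs(self.csd)), 1.0)
        if herm > tol * scale:
            raise ValueError(f"csd not Hermitian: max asymmetry {herm:g}")
        diag = np.diagonal(self.csd, axis1=1, axis2=2)
        if np.min(diag.real) < -tol * scale or np.max(np.abs(diag.imag)) > tol * scale:
            raise ValueError("csd diagonal must be real and nonnegative")


@dataclass
class SpectralFactorization:
    """Minimum-phase spectral factorization S(f) = H(f) Sigma H(f)*."""

    freqs: np.ndarray
    transfer: np.ndarray  # (n_freq, n, n) complex, H(f)
    noise_cov: np.ndarray  # (n, n) real, Sigma
    converged: bool
    iterations: int
    residual: float


@dataclass
class FCSpectra:
    """Per-pair functional connectivity values, frequency resolved.

    For the undirected metrics (``coherence``, ``powcorr``, ``powcorr_ortho``)
    ``values[i, j]`` is symmetric in site order; for ``gc`` it is the
    influence *from* site ``i`` *to* site ``j``.
    """

    fc_type: str
    freqs: np.ndarray
    values: np.ndarray  # (n_sites, n_sites, n_freq)
    n_epochs: int
    mask: Optional[np.ndarray] = None  # boolean (n_sites, n_sites): True = valid

    _ALLOWED = ("coherence", "powcorr", "powcorr_ortho", "gc")

    def __post_init__(self):
        if self.fc_type not in self._ALLOWED:
            raise ValueError(f"fc_type must be one of {self._ALLOWED}")
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def directed(self) -> bool:
        return self.fc_type == "gc"
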