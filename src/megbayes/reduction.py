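"""Spatial and temporal dimensionality reduction of sensor epochs.

The spatial projector U keeps the dominant eigenvectors of the leadfield
Gram matrix L L^T; the temporal projector T keeps the dominant DCT-domain
modes of the spatially reduced data.  Projection compresses the inverse
problem and discards sensor directions and temporal components the forward
model cannot express, which also removes part of the noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct

from .geometry_forward import Leadfield

__all__ = ["ReducedModel", "spatial_projector", "temporal_projector", "reduce_model"]


@dataclass
class ReducedModel:
    """Data and leadfields projected onto spatial and temporal modes.

    U : (u, n_sensors) spatial projector, orthonormal rows
    T : (n_samples, nu) temporal projector, orthonormal columns
    L_reduced : (u, v)
    Y_reduced : (n_trials, u, nu)
    sample_cov : (u, u) trial-averaged reduced covariance,
        mean_t Y_t Y_t^T / nu
    """

    U: np.ndarray
    T: np.ndarray
    L_reduced: np.ndarray
    Y_reduced: np.ndarray
    sample_cov: np.ndarray
    fs_hz: float | None = None

    @property
    def u(self) -> int:
        return self.U.shape[0]

    @property
    def nu(self) -> int:
        return self.T.shape[1]

    @property
    def n_trials(self) -> int:
        return self.Y_reduced.shape[0]

    @property
    def n_effective_samples(self) -> int:
        """Temporal samples behind the pooled covariance (nu * n_trials)."""
        return self.nu * self.n_trials

    def trial_cov(self, t: int) -> np.ndarray:
        y = self.Y_reduced[t]
        return (y @ y.T) / self.nu


def spatial_projector(L: Leadfield | np.ndarray,
                      rel_eigen_tol: float = np.exp(-16.0)) -> np.ndarray:
    """Dominant eigenvectors of L L^T, as rows, ordered by eigenvalue.

    Modes with an eigenvalue below ``rel_eigen_tol`` times the mean
    eigenvalue are removed.
    """
    gain = L.gain if isinstance(L, Leadfield) else np.asarray(L)
    if gain.shape[0] < 2:
        raise ValueError("need at least 2 sensors")
    if not np.all(np.isfinite(gain)):
        raise ValueError("leadfield contains non-finite entries")
    gram = gain @ gain.T
    if not np.any(gram):
        raise ValueError("all-zero leadfield")
    evals, evecs = np.linalg.eigh(gram)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    keep = evals >= rel_eigen_tol * evals.mean()
    return evecs[:, keep].T


def temporal_projector(Y_spatial: np.ndarray,
                       variance_fraction: float | None = None,
                       band: tuple[float, float] | None = None,
                       fs_hz: float | None = None,
                       rel_mean_tol: float = 1.0) -> np.ndarray:
    """Dominant temporal modes of spatially reduced epochs.

    Epochs are DCT-II transformed along time (orthonormal convention), an
    optional frequency band mask is applied, and the eigenvectors of the
    coefficient cross-product define the temporal modes.

    By default the retained modes are the signal subspace: eigenvalues
    above the upper edge of the Marchenko-Pastur noise bulk, with the
    white-noise level estimated by the median eigenvalue.  This removes
    the noise completely whenever the source activity stands above the
    bulk (a handful of modes survive, often just one for a single
    source), while at very low SNR — where no mode clears the edge — the
    selection falls back to keeping every mode at or above
    ``rel_mean_tol`` times the mean eigenvalue, so the reduction degrades
    gracefully instead of discarding a buried signal.  If
    ``variance_fraction`` is given, the smallest mode count whose
    eigenvalue sum reaches that fraction of the total is kept instead.
    The projector T is the inverse DCT of the retained eigenvectors; its
    columns are orthonormal because the DCT is unitary.

    Parameters
    ----------
    Y_spatial : (n_trials, u, n_samples) spatially reduced epochs
    band : optional (lo_hz, hi_hz) window; requires ``fs_hz``
    """
    Y = np.asarray(Y_spatial, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    n_trials, u, n_samples = Y.shape
    if n_trials < 1 or n_samples < 2:
        raise ValueError("need at least one epoch with >= 2 samples")

    X = Y.reshape(n_trials * u, n_samples)
    C = dct(X, type=2, norm="ortho", axis=1)

    if band is not None:
        if fs_hz is None:
            raise ValueError("band selection requires fs_hz")
        lo, hi = band
        # DCT-II bin k represents frequency k * fs / (2 * n_samples)
        freqs = np.arange(n_samples) * fs_hz / (2.0 * n_samples)
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"empty frequency band {band} at fs={fs_hz}")
        C = C * mask[None, :]

    M = C.T @ C
    evals, evecs = np.linalg.eigh(M)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.maximum(evals, 0.0)
    total = evals.sum()
    if total <= 0:
        raise ValueError("zero-variance data")
    if variance_fraction is not None:
        cum = np.cumsum(evals) / total
        nu = int(np.searchsorted(cum, min(variance_fraction, 1.0) - 1e-15) + 1)
    else:
        # Marchenko-Pastur bulk edge for white noise: eigenvalues of an
        # (R x N) noise cross-product concentrate below
        # sigma^2 R (1 + sqrt(N/R))^2; the median estimates sigma^2 R.
        R = X.shape[0]
        edge = np.median(evals) * (1.0 + np.sqrt(n_samples / R)) ** 2
        edge = max(edge, 1e-12 * evals[0])  # noiseless data: drop numerical dust
        nu = int(np.sum(evals > edge))
        if nu == 0:  # noise-dominated: fall back to the mean-eigenvalue rule
            nu = int(np.sum(evals >= rel_mean_tol * evals.mean()))
    nu = int(np.clip(nu, 1, n_samples))
    T = idct(evecs[:, :nu], type=2, norm="ortho", axis=0)
    return T


def reduce_model(B: np.ndarray, U: np.ndarray, T: np.ndarray,
                 L: Leadfield | np.ndarray,
                 fs_hz: float | None = None) -> ReducedModel:
    """Project epochs and leadfield into the reduced space.

    Y_reduced[t] = U B[t] T ;  L_reduced = U L ;
    sample_cov = mean_t Y_t Y_t^T / nu.
    """
    gain = L.gain if isinstance(L, Leadfield) else np.asarray(L)
    B = np.asarray(B, dtype=float)
    if B.ndim == 2:
        B = B[None]
    n_trials, n_sensors, n_samples = B.shape
    if U.shape[1] != n_sensors:
        raise ValueError(f"U expects {U.shape[1]} sensors, data has {n_sensors}")
    if T.shape[0] != n_samples:
        raise ValueError(f"T expects {T.shape[0]} samples, data has {n_samples}")
    if gain.shape[0] != n_sensors:
        raise ValueError("leadfield/sensor count mismatch")

    nu = T.shape[1]
    Y_reduced = np.einsum("un,tns,sj->tuj", U, B, T, optimize=True)
    L_reduced = U @ gain
    sample_cov = np.einsum("tuj,twj->uw", Y_reduced, Y_reduced) / (nu * n_trials)
    sample_cov = 0.5 * (sample_cov + sample_cov.T)
    return ReducedModel(U=U, T=T, L_reduced=L_reduced, Y_reduced=Y_reduced,
                        sample_cov=sample_cov, fs_hz=fs_hz)
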