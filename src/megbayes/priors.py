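"""Source-covariance priors for the four inversion schemes.

Every prior is a covariance component: a PSD source-space matrix Q_i whose
sensor-space projection P_i = L Q_i L^T enters the ReML covariance model.
Components are stored in factored form — a diagonal profile for the global
priors (MNM identity, EBB beamformer variances) and a sparse patch vector
q_i (Q_i = q_i q_i^T) for the multiple-sparse-priors library — so that the
u x u sensor projections stay cheap for hundreds of components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry_forward import GreenSmoother, SourceMesh, mirror_pairs
from .reduction import ReducedModel

__all__ = [
    "CovarianceComponent",
    "PriorLibrary",
    "mnm_prior",
    "ebb_prior",
    "msp_library",
    "noise_component",
    "lcmv_variance_image",
]

_KINDS = {"global_identity", "global_ebb", "patch", "bilateral_patch",
          "sensor_noise", "synthesized"}


@dataclass
class CovarianceComponent:
    """One covariance prior in factored form.

    Exactly one of ``diag_profile`` (v,) or ``patch_profile`` (sparse (v, m)
    column factor, Q = q q^T summed over columns) is set for source-level
    components; both are None for the sensor-noise component (Q = I_u at
    sensor level).
    """

    kind: str
    label: str = ""
    diag_profile: np.ndarray | None = None
    patch_profile: sp.csc_matrix | None = None
    sensor_factor: np.ndarray | None = None  # (u, r): P = F F^T, cached

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")

    # -- sensor-level ----------------------------------------------------

    def sensorize(self, L_reduced: np.ndarray) -> np.ndarray:
        """Cache and return the (u, r) factor F with P = L Q L^T = F F^T."""
        u = L_reduced.shape[0]
        if self.kind == "sensor_noise":
            self.sensor_factor = np.eye(u)
        elif self.diag_profile is not None:
            # P = L diag(d) L^T (+ low-rank part); eigen square root, r = u
            d = np.maximum(self.diag_profile, 0.0)
            P = (L_reduced * d[None, :]) @ L_reduced.T
            if self.patch_profile is not None:
                W = np.asarray(L_reduced @ self.patch_profile)
                P = P + W @ W.T
            w, V = np.linalg.eigh(0.5 * (P + P.T))
            w = np.maximum(w, 0.0)
            self.sensor_factor = V * np.sqrt(w)[None, :]
        elif self.patch_profile is not None:
            self.sensor_factor = np.asarray(L_reduced @ self.patch_profile)
        else:
            raise ValueError(f"component {self.label!r} has no source profile")
        return self.sensor_factor

    @property
    def sensor_projection(self) -> np.ndarray:
        if self.sensor_factor is None:
            raise ValueError("sensorize() the component first")
        return self.sensor_factor @ self.sensor_factor.T

    # -- source-level ----------------------------------------------------

    def source_parts(self, v: int):
        """(diag, lowrank) source representation: Q = diag(d) + R R^T."""
        if self.kind == "sensor_noise":
            raise ValueError("noise component has no source-level covariance")
        d = None
        if self.diag_profile is not None:
            d = np.maximum(self.diag_profile, 0.0)
        return d, self.patch_profile

    @property
    def support(self) -> np.ndarray:
        """Vertex indices with nonzero prior variance."""
        if self.diag_profile is not None:
            return np.flatnonzero(self.diag_profile)
        if self.patch_profile is not None:
            return np.unique(self.patch_profile.indices)
        raise ValueError("sensor-noise component has no source support")


@dataclass
class PriorLibrary:
    """Ordered collection of covariance components (one hyperparameter each)."""

    components: list[CovarianceComponent]
    includes_bilateral: bool = False
    p_per_hemisphere: int = 0
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def sensorize(self, L_reduced: np.ndarray) -> "PriorLibrary":
        for c in self.components:
            c.sensorize(L_reduced)
        return self


def noise_component(label: str = "noise") -> CovarianceComponent:
    """White sensor-noise component, P_0 = I_u."""
    return CovarianceComponent(kind="sensor_noise", label=label)


def mnm_prior(v: int, L_reduced: np.ndarray | None = None) -> CovarianceComponent:
    """Minimum-norm prior: all sources equiprobable and uncorrelated, Q = I_v."""
    if v < 1:
        raise ValueError("need at least one source vertex")
    comp = CovarianceComponent(kind="global_identity", label="mnm",
                               diag_profile=np.ones(v))
    if L_reduced is not None:
        comp.sensorize(L_reduced)
    return comp


def lcmv_variance_image(model: ReducedModel, ridge_rel: float = 1e-8,
                        normalize_leadfields: bool = True) -> np.ndarray:
    """Per-vertex LCMV source-power estimates sigma^2 = (l^T C^-1 l)^-1.

    C is the reduced data covariance, ridge-loaded by ``ridge_rel`` x
    trace(C)/u because few temporal modes can leave it rank-deficient.
    ``normalize_leadfields`` (default on) divides each column by its norm
    first: the unit-gain variant, which removes the 1/||l||^2 depth bias
    that otherwise dominates the variance image at low SNR.  Set it False
    for the raw LCMV power.
    """
    C = model.sample_cov
    u = C.shape[0]
    C = C + (ridge_rel * np.trace(C) / u) * np.eye(u)
    L = model.L_reduced
    if normalize_leadfields:
        L = L / np.maximum(np.linalg.norm(L, axis=0, keepdims=True), 1e-300)
    try:
        Ci_L = np.linalg.solve(C, L)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "reduced covariance singular even after ridge loading") from exc
    quad = np.einsum("uj,uj->j", L, Ci_L)
    if np.any(quad <= 0):
        raise np.linalg.LinAlgError("non-positive beamformer quadratic form")
    return 1.0 / quad


def ebb_prior(model: ReducedModel, ridge_rel: float = 1e-8,
              normalize_leadfields: bool = True) -> CovarianceComponent:
    """Empirical Bayesian beamformer prior.

    A single diagonal source covariance whose entries are the LCMV variance
    estimates from the reduced data covariance (no source correlations
    assumed).
    """
    sigma2 = lcmv_variance_image(model, ridge_rel=ridge_rel,
                                 normalize_leadfields=normalize_leadfields)
    comp = CovarianceComponent(kind="global_ebb", label="ebb",
                               diag_profile=sigma2)
    comp.sensorize(model.L_reduced)
    return comp


def msp_library(G: GreenSmoother, centers: np.ndarray,
                include_bilateral: bool = False,
                mesh: SourceMesh | None = None) -> PriorLibrary:
    """Multiple-sparse-priors patch library.

    One rank-one component q_i q_i^T per centre, q_i the Green-smoother
    column at that centre.  With ``include_bilateral``, one extra component
    q_i + q_mirror(i) per left-hemisphere centre, pairing each left centre
    with the nearest right centre to its mid-sagittal reflection
    (``mesh`` required).
    """
    centers = np.asarray(centers, dtype=np.int64)
    comps = []
    cols = {}
    for c in centers:
        q = G.G[:, int(c)]
        if q.nnz == 0:
            raise ValueError(f"smoother has no column for centre {int(c)}")
        cols[int(c)] = q
        comps.append(CovarianceComponent(kind="patch", label=f"patch:{int(c)}",
                                         patch_profile=sp.csc_matrix(q)))
    p_per_hemisphere = 0
    pairs: list[tuple[int, int]] = []
    if include_bilateral:
        if mesh is None:
            raise ValueError("bilateral priors require the mesh for mirror pairing")
        pairs = mirror_pairs(mesh, centers)
        p_per_hemisphere = len(pairs)
        for left, right in pairs:
            q = sp.csc_matrix(cols[left] + cols[right])
            comps.append(CovarianceComponent(
                kind="bilateral_patch", label=f"bilateral:{left}+{right}",
                patch_profile=q))
    else:
        if mesh is not None:
            p_per_hemisphere = int(np.sum(mesh.hemisphere[centers] == 0))
    return PriorLibrary(components=comps, includes_bilateral=include_bilateral,
                        p_per_hemisphere=p_per_hemisphere, pairs=pairs)
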