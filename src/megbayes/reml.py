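"""Restricted maximum likelihood over covariance components.

The sensor covariance is modelled as C = sum_i exp(lambda_i) P_i +
exp(lambda_0) I_u, with log-scale hyperparameters lambda under Gaussian
hyperpriors N(eta, 1/pi).  Fisher scoring with Levenberg damping maximizes
the Laplace free energy

    F = -N/2 tr(C^-1 S) - N/2 log|C| - uN/2 log 2pi
        - 1/2 (lambda-eta)' Pi (lambda-eta) + 1/2 log|Sigma_lambda Pi|

where S is the sample covariance from N effective temporal samples and
Sigma_lambda the Laplace posterior covariance of the hyperparameters
(inverse expected information).  F is a lower bound on the log model
evidence and is the quantity used to compare prior schemes.

Components are trace-normalized internally (each P_i scaled to trace u)
so that a single log-scale hyperprior is meaningful for patches of very
different leadfield strength; reported ``lambda_mean`` is mapped back to
the raw component scale, while ``lambda_internal`` carries the normalized
values the hyperprior and the ARD prune threshold refer to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .priors import CovarianceComponent

__all__ = [
    "HyperPrior",
    "ReMLResult",
    "MapExtractor",
    "compose_covariance",
    "free_energy",
    "laplace_free_energy",
    "reml",
    "map_extractor",
]

_LAM_CLIP = 64.0  # exp(lambda) clipped to [exp(-64), exp(64)]


@dataclass
class HyperPrior:
    """Gaussian prior on each log-scale hyperparameter."""

    eta: float = -32.0
    pi: float = 1.0 / 256.0

    def __post_init__(self):
        if self.pi <= 0:
            raise ValueError("hyperprior precision pi must be positive")


@dataclass
class ReMLResult:
    lambda_mean: np.ndarray  # raw log-scales: exp() weights the raw components
    lambda_internal: np.ndarray  # trace-normalized log-scales (hyperprior space)
    lambda_cov: np.ndarray  # Laplace posterior covariance Sigma_lambda
    F_trace: np.ndarray
    C_est: np.ndarray
    converged: bool
    n_iter: int
    frozen: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    prune_history: list = field(default_factory=list)

    @property
    def F(self) -> float:
        return float(self.F_trace[-1])


@dataclass
class MapExtractor:
    """Posterior-mean (E-step) source extractor M: S_hat = M Y_reduced."""

    M: np.ndarray  # (v, u)
    noise_scale: float

    def timecourses(self, Y_reduced: np.ndarray) -> np.ndarray:
        return self.M @ Y_reduced

    def power_image(self, sample_cov: np.ndarray) -> np.ndarray:
        """Per-vertex source power diag(M S M^T) from a reduced covariance."""
        X = self.M @ sample_cov
        return np.einsum("vu,vu->v", X, self.M)


# ---------------------------------------------------------------------------
# covariance composition and free energy
# ---------------------------------------------------------------------------


def _factors(components: list[CovarianceComponent], u: int) -> list[np.ndarray]:
    out = []
    for c in components:
        if c.sensor_factor is None:
            if c.kind == "sensor_noise":
                c.sensor_factor = np.eye(u)
            else:
                raise ValueError(f"component {c.label!r} not sensorized")
        if c.sensor_factor.shape[0] != u:
            raise ValueError("component/covariance dimension mismatch")
        out.append(c.sensor_factor)
    return out


def _clip_lam(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam > 700.0):
        warnings.warn("hyperparameter exp overflow; clipping lambda at 700")
        lam = np.minimum(lam, 700.0)
    return lam


def compose_covariance(components: list[CovarianceComponent],
                       lam: np.ndarray, u: int | None = None) -> np.ndarray:
    """C = sum_i exp(lambda_i) P_i (the noise component contributes exp(l) I)."""
    if len(components) != len(np.atleast_1d(lam)):
        raise ValueError("lambda length must match component count")
    if u is None:
        sized = [c.sensor_factor for c in components if c.sensor_factor is not None]
        if not sized:
            raise ValueError("cannot infer dimension u; pass it explicitly")
        u = sized[0].shape[0]
    lam = _clip_lam(lam)
    C = np.zeros((u, u))
    for c, l in zip(_factors(components, u), lam):
        C += np.exp(l) * (c @ c.T)
    return 0.5 * (C + C.T)


def _expected_information(Fs, lam, cho, pi, N):
    """H_ij = N/2 e^li e^lj ||F_i' C^-1 F_j||_F^2 + pi d_ij."""
    ncomp = len(Fs)
    starts = np.cumsum([0] + [f.shape[1] for f in Fs])
    Fcat = np.concatenate(Fs, axis=1)
    Z = cho_solve(cho, Fcat)
    M = Fcat.T @ Z
    M2 = M**2
    # block sums of squares
    H0 = np.add.reduceat(np.add.reduceat(M2, starts[:-1], axis=0),
                         starts[:-1], axis=1)
    e = np.exp(lam)
    H = 0.5 * N * (e[:, None] * e[None, :]) * H0
    H[np.diag_indices(ncomp)] += pi
    return 0.5 * (H + H.T), Z, starts


def free_energy(sample_cov: np.ndarray, nu: float, u: int,
                components: list[CovarianceComponent], lam: np.ndarray,
                lam_cov: np.ndarray, hyperprior: HyperPrior | None = None) -> float:
    """Laplace free energy at the given hyperparameters and posterior covariance.

    Five-term structure: data accuracy, amplitude penalty, dimensional
    constant, hyperprior divergence, and posterior-entropy credit.
    """
    hp = hyperprior or HyperPrior()
    lam = _clip_lam(lam)
    C = compose_covariance(components, lam, u=u)
    sgn, logdet_C = np.linalg.slogdet(C)
    if sgn <= 0:
        raise np.linalg.LinAlgError("composed covariance is singular")
    Ci_S = np.linalg.solve(C, sample_cov)
    d = lam - hp.eta
    n = len(lam)
    sgn_s, logdet_sig = np.linalg.slogdet(np.atleast_2d(lam_cov))
    if sgn_s <= 0:
        raise np.linalg.LinAlgError("hyperparameter covariance is singular")
    return float(
        -0.5 * nu * np.trace(Ci_S)
        - 0.5 * nu * logdet_C
        - 0.5 * u * nu * np.log(2.0 * np.pi)
        - 0.5 * hp.pi * float(d @ d)
        + 0.5 * (logdet_sig + n * np.log(hp.pi))
    )


def laplace_free_energy(sample_cov: np.ndarray, nu: float,
                        components: list[CovarianceComponent],
                        lam: np.ndarray,
                        hyperprior: HyperPrior | None = None) -> float:
    """Free energy with Sigma_lambda set to the inverse expected information.

    This is the objective ReML climbs; it is what the dense grid-search
    oracle evaluates.
    """
    hp = hyperprior or HyperPrior()
    u = sample_cov.shape[0]
    lam = _clip_lam(np.asarray(lam, dtype=float))
    Fs = _factors(components, u)
    C = compose_covariance(components, lam, u=u)
    cho = cho_factor(C + 1e-12 * np.trace(C) / u * np.eye(u))
    H, _, _ = _expected_information(Fs, lam, cho, hp.pi, nu)
    sigma = np.linalg.inv(H)
    return free_energy(sample_cov, nu, u, components, lam, sigma, hp)


# ---------------------------------------------------------------------------
# ReML (Fisher scoring with Levenberg damping)
# ---------------------------------------------------------------------------


def reml(sample_cov: np.ndarray, nu: float,
         components: list[CovarianceComponent],
         hyperprior: HyperPrior | None = None,
         max_iter: int = 512, tol: float = 1e-2,
         prune_threshold: float | None = None,
         max_step: float = 4.0) -> ReMLResult:
    """Estimate hyperparameters of a covariance-component model by ReML.

    Parameters
    ----------
    sample_cov : (u, u) PSD sample covariance
    nu : effective number of temporal samples behind ``sample_cov``
    components : signal components plus exactly one sensor-noise component
    tol : absolute free-energy increase below which iteration stops
    prune_threshold : if set (ARD), components whose internal lambda falls
        below it are frozen and excluded from further updates (the noise
        component is never pruned)
    """
    hp = hyperprior or HyperPrior()
    S = np.asarray(sample_cov, dtype=float)
    u = S.shape[0]
    if S.shape != (u, u):
        raise ValueError("sample_cov must be square")
    w_min = float(np.linalg.eigvalsh(S).min())
    if w_min < -1e-10 * max(np.trace(S), 1.0):
        raise ValueError("sample_cov is not positive semi-definite")
    if nu < 1:
        raise ValueError("nu must be >= 1")
    kinds = [c.kind for c in components]
    if "sensor_noise" not in kinds:
        raise ValueError("a sensor-noise component is required")
    if len(components) < 2:
        raise ValueError("need at least one signal component plus noise")

    Fs_raw = _factors(components, u)
    ncomp = len(components)
    noise_mask = np.array([k == "sensor_noise" for k in kinds])

    # internal trace normalization: each P_i scaled to trace u
    tr = np.array([float((f**2).sum()) for f in Fs_raw])
    if np.any(tr <= 0):
        raise ValueError("component with zero sensor projection")
    scale = u / tr
    log_scale = np.log(scale)
    Fs = [f * np.sqrt(si) for f, si in zip(Fs_raw, scale)]

    trS = float(np.trace(S))
    if trS <= 0:
        raise ValueError("all-zero sample covariance")
    lam = np.full(ncomp, np.log(trS / u) - np.log(ncomp))

    jitter = 1e-12 * trS / u

    def C_of(l):
        C = np.zeros((u, u))
        for f, li in zip(Fs, l):
            C += np.exp(li) * (f @ f.T)
        return 0.5 * (C + C.T)

    def F_of(l):
        C = C_of(l)
        cho = cho_factor(C + jitter * np.eye(u))
        H, Z, starts = _expected_information(Fs, l, cho, hp.pi, nu)
        sgn, logdet_H = np.linalg.slogdet(H)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Ci_S = cho_solve(cho, S)
        d = l - hp.eta
        F = (-0.5 * nu * np.trace(Ci_S) - 0.5 * nu * logdet_C
             - 0.5 * u * nu * np.log(2 * np.pi)
             - 0.5 * hp.pi * float(d @ d)
             + 0.5 * (ncomp * np.log(hp.pi) - logdet_H))
        return F, cho, H, Z, starts

    frozen = np.zeros(ncomp, dtype=bool)
    prune_history: list[tuple[int, int]] = []
    F_trace = []
    damping = 0.0
    converged = False
    F_cur, cho, H, Z, starts = F_of(lam)
    F_trace.append(F_cur)
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        # gradient over all components
        SZ = S @ Z
        e = np.exp(lam)
        g = np.empty(ncomp)
        for i in range(ncomp):
            sl = slice(starts[i], starts[i + 1])
            zi = Z[:, sl]
            t_acc = float(np.einsum("ur,ur->", zi, SZ[:, sl]))
            t_tr = float(np.einsum("ur,ur->", Fs[i], zi))
            g[i] = 0.5 * e[i] * nu * (t_acc - t_tr) - hp.pi * (lam[i] - hp.eta)

        act = ~frozen
        H_aa = H[np.ix_(act, act)]
        g_a = g[act]

        accepted = False
        local_damp = damping
        for _try in range(12):
            Hd = H_aa + local_damp * np.diag(np.diag(H_aa))
            try:
                dl_a = np.linalg.solve(Hd, g_a)
            except np.linalg.LinAlgError:
                local_damp = max(4.0 * local_damp, 1e-4)
                continue
            mx = np.max(np.abs(dl_a))
            if mx > max_step:
                dl_a = dl_a * (max_step / mx)
            lam_new = lam.copy()
            lam_new[act] = np.clip(lam[act] + dl_a, -_LAM_CLIP, _LAM_CLIP)
            try:
                F_new, cho_n, H_n, Z_n, starts_n = F_of(lam_new)
            except np.linalg.LinAlgError:
                local_damp = max(4.0 * local_damp, 1e-4)
                continue
            if F_new >= F_cur - 1e-9 * max(1.0, abs(F_cur)):
                accepted = True
                break
            local_damp = max(4.0 * local_damp, 1e-4)

        if not accepted:
            converged = True  # no ascent direction improves F: at a maximum
            break

        dF = F_new - F_cur
        lam, F_cur, cho, H, Z, starts = lam_new, F_new, cho_n, H_n, Z_n, starts_n
        F_trace.append(F_cur)
        damping = local_damp / 4.0 if local_damp > 0 else 0.0

        if prune_threshold is not None:
            prunable = act & ~noise_mask & (lam < prune_threshold)
            sig_alive = (~frozen) & ~noise_mask
            # never freeze the last surviving signal component
            if prunable.any() and (sig_alive & ~prunable).sum() >= 1:
                frozen |= prunable
                prune_history.append((it, int(prunable.sum())))
                if int((~frozen & ~noise_mask).sum()) == 1:
                    converged = True
                    F_trace.append(F_cur)
                    break

        if 0 <= dF < tol:
            converged = True
            break

    sigma = np.linalg.inv(H)
    lam_raw = lam + log_scale
    C_est = C_of(lam)
    return ReMLResult(lambda_mean=lam_raw, lambda_internal=lam,
                      lambda_cov=sigma, F_trace=np.asarray(F_trace),
                      C_est=C_est, converged=converged, n_iter=n_iter,
                      frozen=frozen, prune_history=prune_history)


# ---------------------------------------------------------------------------
# MAP extraction (E-step)
# ---------------------------------------------------------------------------


def map_extractor(components: list[CovarianceComponent], lam: np.ndarray,
                  L_reduced: np.ndarray) -> MapExtractor:
    """Posterior-mean extractor M = Q L^T (L Q L^T + exp(lambda_0) I)^-1.

    Q = sum over signal components of exp(lambda_i) Q_i at source level;
    ``lam`` is on the raw component scale (``ReMLResult.lambda_mean``).
    """
    lam = _clip_lam(lam)
    u, v = L_reduced.shape
    d_total = np.zeros(v)
    low_cols = []
    lam0 = None
    for c, l in zip(components, lam):
        w = np.exp(l)
        if c.kind == "sensor_noise":
            lam0 = l
            continue
        dg, lowrank = c.source_parts(v)
        if dg is not None:
            d_total += w * dg
        if lowrank is not None:
            low_cols.append(np.sqrt(w) * lowrank)
    if lam0 is None:
        raise ValueError("a sensor-noise component is required")
    R = sp.hstack(low_cols).tocsc() if low_cols else None
    if not np.any(d_total) and (R is None or R.nnz == 0):
        raise ValueError("all-zero source covariance: nothing to extract")

    Cs = np.exp(lam0) * np.eye(u)
    if np.any(d_total):
        Cs += (L_reduced * d_total[None, :]) @ L_reduced.T
    if R is not None:
        W = np.asarray(L_reduced @ R)
        Cs += W @ W.T
    Cs = 0.5 * (Cs + Cs.T)
    Ci = np.linalg.inv(Cs)

    M = np.zeros((v, u))
    if np.any(d_total):
        M += (d_total[:, None] * L_reduced.T) @ Ci
    if R is not None:
        M += np.asarray(R @ (W.T @ Ci))
    if not np.all(np.isfinite(M)):
        raise np.linalg.LinAlgError("non-finite MAP extractor")
    return MapExtractor(M=M, noise_scale=float(np.exp(lam0)))
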