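"""The four inversion drivers: MNM, EBB, ARD and GS.

All schemes share the same final stage: a two-hyperparameter ReML over the
synthesized global source prior plus white sensor noise, followed by the
MAP E-step.  Because the final stage is identical, the resulting free
energies are directly comparable across schemes.

MNM and EBB supply their single global prior directly.  ARD runs one ReML
over the full patch library with per-component hyperparameters and prunes
components whose log-scale falls back to the prior expectation.  GS
maintains a small pool of patch *sets* (one hyperparameter per set),
repeatedly halving the most recent set by MAP magnitude.

The data covariance is trace-normalized per dataset before fitting so the
log-scale hyperpriors sit in a data-independent regime; the MAP extractor
is invariant to this common rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .priors import CovarianceComponent, PriorLibrary, ebb_prior, mnm_prior, noise_component
from .reduction import ReducedModel
from .reml import HyperPrior, MapExtractor, ReMLResult, map_extractor, reml

__all__ = [
    "InversionResult",
    "invert_single_prior",
    "invert_ard",
    "invert_gs",
    "final_inversion",
    "invert",
]

SCHEMES = ("MNM", "EBB", "ARD", "GS")


@dataclass
class InversionResult:
    scheme: str
    image: np.ndarray  # (v,) per-vertex source power (trial-pooled)
    extractor: MapExtractor
    F_final: float
    active_components: list[str]
    lambda_final: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    images_per_trial: np.ndarray | None = None  # (n_trials, v) if per-trial

    def timecourses(self, model: ReducedModel) -> np.ndarray:
        """MAP source time courses of the trial-averaged epoch (v, nu)."""
        return self.extractor.M @ model.Y_reduced.mean(axis=0)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _norm_cov(S: np.ndarray) -> tuple[np.ndarray, float]:
    u = S.shape[0]
    tr = float(np.trace(S))
    if tr <= 0:
        raise ValueError("data covariance has non-positive trace")
    scale = u / tr
    return scale * S, scale


def _final_core(S: np.ndarray, nu_eff: float, model: ReducedModel,
                synth: CovarianceComponent, hyperprior: HyperPrior,
                tol: float, max_iter: int) -> tuple[MapExtractor, float, ReMLResult]:
    """Two-hyperparameter ReML + E-step on an already-normalized covariance."""
    if synth.sensor_factor is None:
        synth.sensorize(model.L_reduced)
    noise = noise_component()
    noise.sensorize(model.L_reduced)
    comps = [synth, noise]
    res = reml(S, nu_eff, comps, hyperprior=hyperprior, tol=tol,
               max_iter=max_iter)
    extractor = map_extractor(comps, res.lambda_mean, model.L_reduced)
    return extractor, res.F, res


def final_inversion(model: ReducedModel, synthesized_prior: CovarianceComponent,
                    nu_eff: float | None = None,
                    hyperprior: HyperPrior | None = None,
                    tol: float = 1e-2, max_iter: int = 512,
                    ) -> tuple[MapExtractor, float]:
    """Common stage 4: re-weight the synthesized source prior against noise.

    The free energy returned is computed by the same two-hyperparameter
    model whatever scheme produced the prior, so values are comparable, and
    it is invariant to a rescaling of the synthesized prior (the scale is
    absorbed by its hyperparameter).
    """
    hp = hyperprior or HyperPrior()
    S, _ = _norm_cov(model.sample_cov)
    if nu_eff is None:
        nu_eff = model.n_effective_samples
    extractor, F, _ = _final_core(S, nu_eff, model, synthesized_prior, hp,
                                  tol, max_iter)
    return extractor, F


# ---------------------------------------------------------------------------
# MNM / EBB
# ---------------------------------------------------------------------------


def invert_single_prior(model: ReducedModel, prior: CovarianceComponent,
                        hyperprior: HyperPrior | None = None,
                        per_trial: bool = False,
                        tol: float = 1e-2, max_iter: int = 512) -> InversionResult:
    """Invert with a single global prior (MNM identity or EBB beamformer).

    For these schemes stage 3 (prior weighting) is trivial — there is only
    one source prior — so the inversion is exactly the common final stage.
    """
    if prior.kind not in ("global_identity", "global_ebb"):
        raise ValueError(f"expected a global prior, got kind {prior.kind!r}")
    scheme = "MNM" if prior.kind == "global_identity" else "EBB"
    hp = hyperprior or HyperPrior()

    def run(S, nu_eff):
        Sn, _ = _norm_cov(S)
        ext, F, res = _final_core(Sn, nu_eff, model, prior, hp, tol, max_iter)
        return ext, F, res

    return _drive(scheme, model, run, per_trial,
                  active=[prior.label], extra={})


def _drive(scheme: str, model: ReducedModel, run, per_trial: bool,
           active: list[str], extra: dict) -> InversionResult:
    if not per_trial:
        ext, F, res = run(model.sample_cov, model.n_effective_samples)
        image = ext.power_image(model.sample_cov)
        diag = {"n_iter": res.n_iter, "converged": res.converged,
                "F_trace": res.F_trace, **extra}
        return InversionResult(scheme=scheme, image=image, extractor=ext,
                               F_final=F, active_components=active,
                               lambda_final=res.lambda_mean, diagnostics=diag)
    images, Fs = [], []
    last = None
    for t in range(model.n_trials):
        St = model.trial_cov(t)
        ext, F, res = run(St, model.nu)
        images.append(ext.power_image(St))
        Fs.append(F)
        last = (ext, res)
    images = np.asarray(images)
    ext, res = last
    diag = {"n_iter": res.n_iter, "converged": res.converged,
            "F_per_trial": np.asarray(Fs), **extra}
    return InversionResult(scheme=scheme, image=images.mean(axis=0),
                           extractor=ext, F_final=float(np.sum(Fs)),
                           active_components=active,
                           lambda_final=res.lambda_mean, diagnostics=diag,
                           images_per_trial=images)


# ---------------------------------------------------------------------------
# ARD
# ---------------------------------------------------------------------------


def _synthesize(components: list[CovarianceComponent], weights: np.ndarray,
                v: int, label: str) -> CovarianceComponent:
    """Weighted sum of source covariances as one synthesized component."""
    d_total = np.zeros(v)
    any_d = False
    cols = []
    for c, w in zip(components, weights):
        if w <= 0:
            continue
        dg, lowrank = c.source_parts(v)
        if dg is not None:
            d_total += w * dg
            any_d = True
        if lowrank is not None:
            cols.append(np.sqrt(w) * lowrank)
    return CovarianceComponent(
        kind="synthesized", label=label,
        diag_profile=d_total if any_d else None,
        patch_profile=sp.hstack(cols).tocsc() if cols else None)


def invert_ard(model: ReducedModel, library: PriorLibrary,
               hyperprior: HyperPrior | None = None,
               per_trial: bool = False,
               prune_offset: float = 2.0,
               tol: float = 1e-2, max_iter: int = 512) -> InversionResult:
    """Automatic relevance determination over the full patch library.

    One hyperparameter per component; components whose (normalized)
    log-scale falls below eta + ``prune_offset`` are discarded from the
    active set.  The surviving weighted components are summed into a global
    prior for the common final inversion.
    """
    if len(library) == 0:
        raise ValueError("empty prior library")
    hp = hyperprior or HyperPrior()
    v = model.L_reduced.shape[1]
    library.sensorize(model.L_reduced)
    threshold = hp.eta + prune_offset

    def run(S, nu_eff):
        Sn, _ = _norm_cov(S)
        noise = noise_component()
        comps = list(library.components) + [noise]
        res = reml(Sn, nu_eff, comps, hyperprior=hp, tol=tol,
                   max_iter=max_iter, prune_threshold=threshold)
        lam_sig = res.lambda_internal[:-1]
        alive = (~res.frozen[:-1]) & (lam_sig >= threshold)
        if not alive.any():
            alive[np.argmax(lam_sig)] = True
        weights = np.where(alive, np.exp(res.lambda_mean[:-1]), 0.0)
        synth = _synthesize(library.components, weights, v, "ard")
        ext, F, final_res = _final_core(Sn, nu_eff, model, synth, hp, tol,
                                        max_iter)
        run.last = (alive, res)
        return ext, F, final_res

    ext_active: list[str] = []
    result = _drive("ARD", model, run, per_trial, active=ext_active, extra={})
    alive, ard_res = run.last
    result.active_components = [c.label for c, a in
                                zip(library.components, alive) if a]
    result.diagnostics.update({
        "ard_n_iter": ard_res.n_iter,
        "ard_converged": ard_res.converged,
        "ard_F_trace": ard_res.F_trace,
        "prune_history": ard_res.prune_history,
        "n_active": int(alive.sum()),
    })
    return result


# ---------------------------------------------------------------------------
# GS
# ---------------------------------------------------------------------------


def invert_gs(model: ReducedModel, library: PriorLibrary,
              hyperprior: HyperPrior | None = None,
              per_trial: bool = False,
              max_pool: int = 8, min_pool_keep: int = 3,
              f_tol: float = 1e-2, max_outer: int = 32,
              tol: float = 1e-2, max_iter: int = 512) -> InversionResult:
    """Greedy search over sets of patch priors.

    Each candidate set is one summed covariance component with a single
    hyperparameter.  The first set contains every component with equal
    variance; at each outer iteration the members of the newest set are
    ordered by MAP magnitude and its top half becomes a new set appended to
    the pool.  Sets whose hyperparameter collapses to the prior expectation
    are dropped (pool capped at ``max_pool``, oldest evicted first).  The
    search stops when the free energy stops increasing for two consecutive
    iterations or the newest set has a single member.
    """
    if len(library) == 0:
        raise ValueError("empty prior library")
    hp = hyperprior or HyperPrior()
    v = model.L_reduced.shape[1]
    library.sensorize(model.L_reduced)
    threshold = hp.eta + 2.0
    patches = library.components
    n = len(patches)
    W = np.concatenate([c.sensor_factor for c in patches], axis=1)  # (u, n)
    Q = sp.hstack([c.patch_profile for c in patches]).tocsc()  # (v, n)
    support = (abs(Q) > 0).astype(float)  # (v, n) pattern

    def set_component(idx: np.ndarray) -> CovarianceComponent:
        comp = CovarianceComponent(kind="synthesized",
                                   label=f"set[{len(idx)}]",
                                   patch_profile=Q[:, idx])
        comp.sensor_factor = W[:, idx]
        return comp

    def run(S, nu_eff):
        Sn, _ = _norm_cov(S)
        pool: list[np.ndarray] = [np.arange(n)]
        F_prev = -np.inf
        stall = 0
        history = []
        best = None  # (F, ReMLResult, pool snapshot) of the best outer step
        for outer in range(1, max_outer + 1):
            comps = [set_component(idx) for idx in pool] + [noise_component()]
            res = reml(Sn, nu_eff, comps, hyperprior=hp, tol=tol,
                       max_iter=max_iter)
            F_outer = res.F
            if best is None or F_outer > best[0]:
                best = (F_outer, res, [ix.copy() for ix in pool])
            history.append((outer, [len(ix) for ix in pool], F_outer))

            if F_outer - F_prev < f_tol:
                stall += 1
                if stall >= 2:
                    break
            else:
                stall = 0
            F_prev = max(F_prev, F_outer)
            if len(pool[-1]) == 1:
                break

            # E-step: per-patch magnitudes under the current weighted prior
            weights = np.exp(res.lambda_mean[:-1])
            omega = np.zeros(n)
            for idx, w in zip(pool, weights):
                omega[idx] += w
            synth = _synthesize_from_weights(Q, omega, "gs-estep")
            ext = map_extractor([synth, noise_component()],
                                np.array([0.0, res.lambda_mean[-1]]),
                                model.L_reduced)
            image = ext.power_image(Sn)
            mag = support.T @ image  # sum of squared MAP estimates per support

            parent = pool[-1]
            order = parent[np.argsort(mag[parent])[::-1]]
            new_set = np.sort(order[: int(np.ceil(len(parent) / 2))])

            # prune unsupported sets, never the best one, keep a small pool
            lam_int = res.lambda_internal[:-1]
            top_set = int(np.argmax(lam_int))
            keep = [i for i in range(len(pool))
                    if lam_int[i] >= threshold or i == top_set]
            if len(keep) > min_pool_keep:
                pool = [pool[i] for i in keep]
                lam_int = lam_int[keep]
            pool.append(new_set)
            while len(pool) > max_pool:
                pool.pop(0)

        # synthesize from the best-F pool weighting
        _, best_res, best_pool = best
        weights = np.exp(best_res.lambda_mean[:-1])
        lam_int = best_res.lambda_internal[:-1]
        omega = np.zeros(n)
        for idx, w in zip(best_pool, weights):
            omega[idx] += w
        synth = _synthesize_from_weights(Q, omega, "gs")
        ext, F, final_res = _final_core(Sn, nu_eff, model, synth, hp, tol,
                                        max_iter)
        supported = [i for i in range(len(best_pool))
                     if lam_int[i] >= threshold]
        if not supported:
            supported = [int(np.argmax(lam_int))]
        active_idx = np.unique(np.concatenate(
            [best_pool[i] for i in supported]))
        run.last = (active_idx, history, best_res)
        return ext, F, final_res

    result = _drive("GS", model, run, per_trial, active=[], extra={})
    active_idx, history, gs_res = run.last
    result.active_components = [patches[i].label for i in active_idx]
    result.diagnostics.update({
        "gs_history": history,
        "gs_converged": gs_res.converged,
        "n_active": len(active_idx),
    })
    return result


def _synthesize_from_weights(Q: sp.csc_matrix, omega: np.ndarray,
                             label: str) -> CovarianceComponent:
    nz = np.flatnonzero(omega > 0)
    if len(nz) == 0:
        raise ValueError("GS produced an empty prior set")
    R = Q[:, nz] @ sp.diags(np.sqrt(omega[nz]))
    return CovarianceComponent(kind="synthesized", label=label,
                               patch_profile=R.tocsc())


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def invert(model: ReducedModel, scheme: str,
           library: PriorLibrary | None = None,
           hyperprior: HyperPrior | None = None,
           per_trial: bool = False, **kwargs) -> InversionResult:
    """Run one of the four schemes by name."""
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "MNM":
        prior = mnm_prior(model.L_reduced.shape[1], model.L_reduced)
        return invert_single_prior(model, prior, hyperprior, per_trial, **kwargs)
    if scheme == "EBB":
        prior = ebb_prior(model)
        return invert_single_prior(model, prior, hyperprior, per_trial, **kwargs)
    if library is None:
        raise ValueError(f"{scheme} requires a patch prior library")
    if scheme == "ARD":
        return invert_ard(model, library, hyperprior, per_trial, **kwargs)
    return invert_gs(model, library, hyperprior, per_trial, **kwargs)
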