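"""FROC-style localization accuracy (SAI) and temporal accuracy (TAI).

SAI: local maxima of the per-vertex power image are walked in descending
magnitude; within a search radius r of a true dipole a peak is a true
positive, otherwise a false positive.  The accumulated-magnitude positive
predictive value Y = TP_acc / (TP_acc + FP_acc) traced against the
fraction of peaks visited gives, by trapezoidal area, a spatial accuracy
index in [0, 1] per search size (1 = no false positives, 0 = no true
positives).

TAI: the coefficient of determination R^2 of the reduced sensor data
explained by the reconstructed sources within r of the true dipoles,
summarized across the log-spaced search sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_forward import SourceMesh
from .reduction import ReducedModel

__all__ = [
    "PeakSet",
    "SAIReport",
    "TAIReport",
    "default_search_sizes",
    "find_local_maxima",
    "compute_sai",
    "sai_of_result",
    "compute_tai",
    "compare_accuracy",
    "compare_free_energy",
]


def default_search_sizes(n: int = 10, lo_mm: float = 3.0,
                         hi_mm: float = 30.0) -> np.ndarray:
    """Log-spaced search radii, 3 to 30 mm by default."""
    return np.geomspace(lo_mm, hi_mm, n)


@dataclass
class PeakSet:
    peak_vertices: np.ndarray  # sorted by descending value
    peak_values: np.ndarray
    rel_threshold: float = 0.05


@dataclass
class SAIReport:
    search_sizes_mm: np.ndarray
    ppv_curves: list  # per search size: (fractions, Y) arrays
    sai: np.ndarray  # AUC per search size, in [0, 1]


@dataclass
class TAIReport:
    search_sizes_mm: np.ndarray
    tai_at_size: np.ndarray  # R^2 per search size (NaN when undefined)
    tai_auc: float


# ---------------------------------------------------------------------------
# peaks and SAI
# ---------------------------------------------------------------------------


def find_local_maxima(image: np.ndarray, mesh: SourceMesh,
                      rel_threshold: float = 0.05) -> PeakSet:
    """Local maxima of a per-vertex image over the mesh neighbour graph.

    A vertex is a peak iff its value exceeds all first-order neighbours
    (ties broken toward the lower index); peaks below ``rel_threshold`` of
    the global peak are discarded; the result is sorted by descending value.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] != mesh.n_vertices:
        raise ValueError("image length must equal the vertex count")
    if not np.any(image):
        return PeakSet(np.empty(0, int), np.empty(0), rel_threshold)

    adj = mesh.adjacency
    indptr, indices = adj.indptr, adj.indices
    is_peak = np.ones(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        nb = indices[indptr[v]:indptr[v + 1]]
        val = image[v]
        nv = image[nb]
        if np.any(nv > val) or np.any((nv == val) & (nb < v)):
            is_peak[v] = False
    peaks = np.flatnonzero(is_peak)
    vals = image[peaks]
    keep = vals >= rel_threshold * vals.max()
    peaks, vals = peaks[keep], vals[keep]
    order = np.argsort(vals)[::-1]
    return PeakSet(peaks[order], vals[order], rel_threshold)


def compute_sai(peaks: PeakSet, true_vertices: np.ndarray, mesh: SourceMesh,
                search_sizes: np.ndarray | None = None) -> SAIReport:
    """Accumulated-magnitude PPV curves and their AUC per search size.

    Distances are Euclidean (mm) from a peak to the nearest true dipole.
    The AUC abscissa is the fraction of the total peak count; the curve is
    extended flat to fraction 0 so that an all-true-positive peak list
    scores exactly 1.
    """
    true_vertices = np.atleast_1d(np.asarray(true_vertices, dtype=np.int64))
    if len(true_vertices) == 0:
        raise ValueError("need at least one true vertex")
    if search_sizes is None:
        search_sizes = default_search_sizes()
    search_sizes = np.asarray(search_sizes, dtype=float)

    if len(peaks.peak_vertices) == 0:
        curves = [(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
                  for _ in search_sizes]
        return SAIReport(search_sizes, curves, np.zeros(len(search_sizes)))

    ppos = mesh.vertices[peaks.peak_vertices]
    tpos = mesh.vertices[true_vertices]
    dist = np.min(np.linalg.norm(ppos[:, None, :] - tpos[None, :, :], axis=2),
                  axis=1)
    k = len(peaks.peak_vertices)
    fr = np.arange(1, k + 1) / k

    curves, aucs = [], []
    for r in search_sizes:
        tp = dist <= r
        mag_tp = np.cumsum(np.where(tp, peaks.peak_values, 0.0))
        mag_fp = np.cumsum(np.where(~tp, peaks.peak_values, 0.0))
        Y = mag_tp / (mag_tp + mag_fp)
        x = np.concatenate([[0.0], fr])
        y = np.concatenate([[Y[0]], Y])
        curves.append((x, y))
        aucs.append(np.trapezoid(y, x))
    return SAIReport(search_sizes, curves, np.asarray(aucs))


def sai_of_result(image: np.ndarray, true_vertices, mesh: SourceMesh,
                  search_sizes=None, rel_threshold: float = 0.05) -> SAIReport:
    """Convenience: peak detection + SAI in one call (single image)."""
    peaks = find_local_maxima(image, mesh, rel_threshold)
    return compute_sai(peaks, true_vertices, mesh, search_sizes)


# ---------------------------------------------------------------------------
# TAI
# ---------------------------------------------------------------------------


def compute_tai(result, model: ReducedModel, true_vertices: np.ndarray,
                mesh: SourceMesh, search_sizes: np.ndarray | None = None,
                peaks: PeakSet | None = None,
                rel_threshold: float = 0.05) -> TAIReport:
    """Variance of the reduced data explained by the true-positive sources.

    For each search size r, the image peaks within r of any true dipole
    (the true positives of the spatial scoring) contribute their MAP time
    courses s_hat = M_p Y as regressors; R^2 = 1 - SS_res/SS_tot is the
    fraction of reduced-data variance captured by projecting each trial
    onto the span of those time courses.  Because the regressor span only
    grows with r, the R^2 curve is non-decreasing in the search size.

    R^2 is reported as NaN when a single temporal mode survives the
    reduction: with one time sample any non-zero regressor explains the
    data exactly, so the quantity is uninformative.

    ``tai_auc`` is the trapezoidal area of the R^2 curve over the log-r
    axis normalized to [0, 1].  ``result`` may be an InversionResult or a
    bare (v, u) extractor matrix; ``peaks`` defaults to the local maxima
    of ``result.image``.
    """
    M = getattr(getattr(result, "extractor", result), "M", None)
    if M is None:
        M = np.asarray(result)
    true_vertices = np.atleast_1d(np.asarray(true_vertices, dtype=np.int64))
    if len(true_vertices) == 0:
        raise ValueError("need at least one true vertex")
    if search_sizes is None:
        search_sizes = default_search_sizes()
    search_sizes = np.asarray(search_sizes, dtype=float)

    ss_tot = model.nu * model.n_trials * float(np.trace(model.sample_cov))
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares in the reduced data")
    if model.nu < 2:
        nan = np.full(len(search_sizes), np.nan)
        return TAIReport(search_sizes, nan, float("nan"))

    if peaks is None:
        image = getattr(result, "image", None)
        if image is None:
            raise ValueError("pass `peaks` when result carries no image")
        peaks = find_local_maxima(image, mesh, rel_threshold)
    if len(peaks.peak_vertices) == 0:
        zero = np.zeros(len(search_sizes))
        return TAIReport(search_sizes, zero, 0.0)

    tpos = mesh.vertices[true_vertices]
    pdist = np.min(np.linalg.norm(
        mesh.vertices[peaks.peak_vertices][:, None, :] - tpos[None, :, :],
        axis=2), axis=1)

    # per-trial MAP time courses of every peak, (n_trials, n_peaks, nu)
    Z = np.einsum("pu,tuj->tpj", M[peaks.peak_vertices], model.Y_reduced)

    r2 = np.empty(len(search_sizes))
    for i, r in enumerate(search_sizes):
        sel = np.flatnonzero(pdist <= r)
        if len(sel) == 0:
            r2[i] = 0.0
            continue
        explained = 0.0
        for t in range(model.n_trials):
            Zt = Z[t, sel]  # (k, nu)
            Yt = model.Y_reduced[t]  # (u, nu)
            B = Yt @ Zt.T  # (u, k)
            Gram = Zt @ Zt.T
            coeff = B @ np.linalg.pinv(Gram, rcond=1e-12)
            explained += float(np.einsum("uk,uk->", coeff, B))
        r2[i] = 1.0 - (ss_tot - explained) / ss_tot
    if len(search_sizes) < 2:
        return TAIReport(search_sizes, r2, float(r2[0]))
    x = np.log(search_sizes)
    x = (x - x[0]) / (x[-1] - x[0])
    return TAIReport(search_sizes, r2, float(np.trapezoid(r2, x)))


# ---------------------------------------------------------------------------
# cross-scheme statistics
# ---------------------------------------------------------------------------


def compare_accuracy(scores: pd.DataFrame, alpha: float = 0.05,
                     score_col: str = "score") -> dict:
    """Pairwise two-sample t-tests between schemes, Bonferroni corrected.

    ``scores`` needs columns scheme / condition / snr_db / <score_col>, one
    row per simulation.  The Bonferroni factor is (number of conditions) x
    (number of SNR levels).  Returns a dict with a per-cell mean +- SEM
    table and a pairwise-test table.
    """
    required = {"scheme", "condition", "snr_db", score_col}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores must have columns {sorted(required)}")
    conditions = sorted(scores["condition"].unique())
    snrs = sorted(scores["snr_db"].unique())
    bonf = len(conditions) * len(snrs)

    cells = (scores.groupby(["scheme", "condition", "snr_db"])[score_col]
             .agg(["mean", "sem", "count"]).reset_index())

    rows = []
    for cond in conditions:
        for snr in snrs:
            cell = scores[(scores["condition"] == cond)
                          & (scores["snr_db"] == snr)]
            schemes = sorted(cell["scheme"].unique())
            for a, b in itertools.combinations(schemes, 2):
                xa = cell.loc[cell["scheme"] == a, score_col].to_numpy()
                xb = cell.loc[cell["scheme"] == b, score_col].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                degenerate = xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0
                if degenerate and np.allclose(xa.mean(), xb.mean()):
                    t, p = 0.0, 1.0
                elif degenerate:
                    t, p = np.inf, 0.0
                else:
                    t, p = stats.ttest_ind(xa, xb)
                rows.append({
                    "condition": cond, "snr_db": snr, "scheme_a": a,
                    "scheme_b": b, "t": float(t), "p": float(p),
                    "p_bonferroni": float(min(1.0, p * bonf)),
                    "significant": bool(p * bonf < alpha),
                    "degenerate": bool(degenerate),
                })
    return {"cells": cells, "tests": pd.DataFrame(rows),
            "bonferroni_factor": bonf, "alpha": alpha}


def compare_free_energy(F_table: pd.DataFrame, log=None) -> pd.DataFrame:
    """Fixed-effects pairwise free-energy comparison across simulations.

    ``F_table``: one row per simulation, one column per scheme.  Rows with
    missing values are dropped (reported via ``log`` if given).  Returns
    per-pair mean F difference, sign counts and the fraction of simulations
    favouring each scheme.
    """
    complete = F_table.dropna()
    dropped = len(F_table) - len(complete)
    if dropped and log is not None:
        log(f"compare_free_energy: dropped {dropped} incomplete rows")
    rows = []
    for a, b in itertools.combinations(complete.columns, 2):
        d = complete[a] - complete[b]
        n = len(d)
        wins_a = int((d > 0).sum())
        wins_b = int((d < 0).sum())
        ties = n - wins_a - wins_b
        frac_a = (wins_a + 0.5 * ties) / n if n else np.nan
        rows.append({"scheme_a": a, "scheme_b": b,
                     "mean_dF": float(d.mean()) if n else np.nan,
                     "wins_a": wins_a, "wins_b": wins_b, "ties": ties,
                     "fraction_favoring_a": frac_a, "n": n})
    return pd.DataFrame(rows)
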