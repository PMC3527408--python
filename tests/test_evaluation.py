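"""SAI/TAI metrics and cross-scheme statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from megbayes import invert
from megbayes.evaluation import (PeakSet, compare_accuracy, compare_free_energy,
                                 compute_sai, compute_tai, default_search_sizes,
                                 find_local_maxima)
from tests.conftest import make_model


# ---------------------------------------------------------------------------
# local maxima
# ---------------------------------------------------------------------------


def _peaks_bruteforce(image, mesh, rel_threshold=0.05):
    adj = mesh.adjacency
    out = []
    for v in range(mesh.n_vertices):
        nb = adj.indices[adj.indptr[v]:adj.indptr[v + 1]]
        better = [w for w in nb if image[w] > image[v]
                  or (image[w] == image[v] and w < v)]
        if not better:
            out.append(v)
    out = [v for v in out if image[v] >= rel_threshold * max(image[v2] for v2 in out)]
    return sorted(out, key=lambda v: -image[v])


def test_single_nonzero_vertex_is_single_peak(small_head):
    mesh, _ = small_head
    image = np.zeros(mesh.n_vertices)
    image[17] = 3.0
    peaks = find_local_maxima(image, mesh)
    assert list(peaks.peak_vertices) == [17]
    assert find_local_maxima(np.zeros(mesh.n_vertices), mesh).peak_vertices.size == 0


def test_small_peaks_below_relative_threshold_removed(small_head):
    mesh, _ = small_head
    image = np.zeros(mesh.n_vertices)
    image[5] = 100.0
    image[300] = 4.0  # below 5% of 100
    peaks = find_local_maxima(image, mesh, rel_threshold=0.05)
    assert list(peaks.peak_vertices) == [5]


def test_peaks_agree_with_bruteforce_oracle(small_head):
    mesh, _ = small_head
    rng = np.random.default_rng(0)
    for _ in range(20):
        image = rng.exponential(size=mesh.n_vertices)
        got = find_local_maxima(image, mesh)
        expect = _peaks_bruteforce(image, mesh)
        assert list(got.peak_vertices) == expect


# ---------------------------------------------------------------------------
# SAI
# ---------------------------------------------------------------------------


def _sai_bruteforce(vertices, values, truth, mesh, r):
    """Step-by-step accumulation oracle for one search size."""
    order = np.argsort(values)[::-1]
    tp_acc = fp_acc = 0.0
    xs, ys = [0.0], [None]
    k = len(vertices)
    for step, i in enumerate(order, start=1):
        d = min(np.linalg.norm(mesh.vertices[vertices[i]] - mesh.vertices[t])
                for t in truth)
        if d <= r:
            tp_acc += values[i]
        else:
            fp_acc += values[i]
        xs.append(step / k)
        ys.append(tp_acc / (tp_acc + fp_acc))
    ys[0] = ys[1]
    return np.trapezoid(ys, xs)


def test_sai_limits(small_head):
    mesh, _ = small_head
    truth = [40]
    near = mesh.adjacency.indices[
        mesh.adjacency.indptr[40]:mesh.adjacency.indptr[41]][:2]
    peaks = PeakSet(np.array([40, near[0]]), np.array([5.0, 2.0]))
    rep = compute_sai(peaks, truth, mesh, [30.0])
    assert rep.sai[0] == pytest.approx(1.0)  # all peaks are true positives
    far = int(np.argmax(np.linalg.norm(mesh.vertices - mesh.vertices[40], axis=1)))
    rep0 = compute_sai(PeakSet(np.array([far]), np.array([1.0])), truth, mesh, [5.0])
    assert rep0.sai[0] == 0.0
    empty = compute_sai(PeakSet(np.empty(0, int), np.empty(0)), truth, mesh, [5.0])
    assert np.all(empty.sai == 0.0)


def test_sai_handworked_three_peak_case(small_head):
    """TP(10), FP(5), TP(5): Y = 1, 10/15, 15/20 against the step oracle."""
    mesh, _ = small_head
    truth = [40]
    nb = mesh.adjacency.indices[mesh.adjacency.indptr[40]:mesh.adjacency.indptr[41]]
    far = int(np.argmax(np.linalg.norm(mesh.vertices - mesh.vertices[40], axis=1)))
    vertices = np.array([40, far, nb[0]])
    values = np.array([10.0, 5.0, 5.0 - 1e-9])  # tie-break: FP walks first
    r = 1.5 * np.linalg.norm(mesh.vertices[nb[0]] - mesh.vertices[40])
    assert np.linalg.norm(mesh.vertices[far] - mesh.vertices[40]) > r
    peaks = PeakSet(vertices, values)
    rep = compute_sai(peaks, truth, mesh, [r])
    _, Y = rep.ppv_curves[0]
    assert np.allclose(Y, [1.0, 1.0, 10.0 / 15.0, 15.0 / 20.0], atol=1e-9)
    oracle = _sai_bruteforce(vertices, values, truth, mesh, r)
    assert rep.sai[0] == pytest.approx(oracle, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_sai_matches_bruteforce_on_random_instances(small_head, data):
    mesh, _ = small_head
    n_peaks = data.draw(st.integers(1, 10))
    n_truth = data.draw(st.integers(1, 3))
    rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
    vertices = rng.choice(mesh.n_vertices, n_peaks, replace=False)
    values = rng.uniform(0.5, 10.0, n_peaks)
    truth = rng.choice(mesh.n_vertices, n_truth, replace=False)
    order = np.argsort(values)[::-1]
    peaks = PeakSet(vertices[order], values[order])
    sizes = default_search_sizes()
    rep = compute_sai(peaks, truth, mesh, sizes)
    for i, r in enumerate(sizes):
        assert rep.sai[i] == pytest.approx(
            _sai_bruteforce(vertices, values, truth, mesh, r), abs=1e-12)
    # monotone in search size: enlarging r can only convert FP -> TP
    assert np.all(np.diff(rep.sai) >= -1e-12)
    assert np.all((0.0 <= rep.sai) & (rep.sai <= 1.0))


# ---------------------------------------------------------------------------
# TAI
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def two_source_run(small_head, small_leadfield, small_centers, small_locations,
                   small_projector, small_library):
    mesh, _ = small_head
    ds, model = make_model(mesh, small_leadfield, small_centers,
                           small_locations, small_projector,
                           snr_db=0.0, seed=31, n_trials=30,
                           n_dipoles=2, placement="asymmetric_pair",
                           correlation_regime="low")
    res = invert(model, "ARD", library=small_library)
    return mesh, ds, model, res


def test_tai_monotone_and_bounded(two_source_run):
    mesh, ds, model, res = two_source_run
    rep = compute_tai(res, model, ds.true_vertices, mesh)
    assert model.nu >= 2
    assert np.all(np.diff(rep.tai_at_size) >= -1e-9)
    assert np.all(rep.tai_at_size <= 1.0 + 1e-12)
    assert 0.0 <= rep.tai_auc <= 1.0 + 1e-12


def test_tai_perfect_reconstruction_scores_one(small_head):
    """If TP time courses span the data, every covering radius gives R^2 = 1."""
    mesh, _ = small_head
    rng = np.random.default_rng(2)
    u, nu, v = 6, 8, mesh.n_vertices
    from megbayes.reduction import ReducedModel
    Y = rng.normal(size=(1, u, nu))
    nb = mesh.adjacency.indices[mesh.adjacency.indptr[40]:mesh.adjacency.indptr[41]]
    span = np.concatenate([[40], nb])[: u + 1]
    M = np.zeros((v, u))
    M[span] = rng.normal(size=(len(span), u))  # TP sources span sensor space
    model = ReducedModel(U=np.eye(u), T=np.eye(nu)[:, :nu],
                         L_reduced=rng.normal(size=(u, v)), Y_reduced=Y,
                         sample_cov=(Y[0] @ Y[0].T) / nu)
    r = 1.1 * max(np.linalg.norm(mesh.vertices[s] - mesh.vertices[40])
                  for s in span)
    peaks = PeakSet(span, np.linspace(2.0, 1.0, len(span)))
    rep = compute_tai(M, model, [40], mesh, [r], peaks=peaks)
    assert rep.tai_at_size[0] == pytest.approx(1.0, abs=1e-9)


def test_tai_zero_reconstruction_scores_zero(two_source_run):
    mesh, ds, model, _ = two_source_run
    v = mesh.n_vertices
    M = np.zeros((v, model.u))
    image = np.zeros(v)
    image[ds.true_vertices[0]] = 1.0
    peaks = find_local_maxima(image, mesh)
    rep = compute_tai(M, model, ds.true_vertices, mesh, [30.0], peaks=peaks)
    assert rep.tai_at_size[0] == pytest.approx(0.0, abs=1e-12)


def test_tai_undefined_for_single_temporal_mode(two_source_run, small_head):
    mesh, ds, model, res = two_source_run
    from megbayes.reduction import ReducedModel
    squeezed = ReducedModel(U=model.U, T=model.T[:, :1],
                            L_reduced=model.L_reduced,
                            Y_reduced=model.Y_reduced[:, :, :1],
                            sample_cov=model.sample_cov)
    rep = compute_tai(res, squeezed, ds.true_vertices, mesh)
    assert np.all(np.isnan(rep.tai_at_size))
    assert np.isnan(rep.tai_auc)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _scores_frame(rows):
    return pd.DataFrame(rows, columns=["scheme", "condition", "snr_db", "score"])


def test_compare_accuracy_identical_scores_never_significant():
    rows = [(s, "c1", snr, 0.5) for s in ("A", "B") for snr in (0, 10)
            for _ in range(5)]
    out = compare_accuracy(_scores_frame(rows))
    assert not out["tests"]["significant"].any()
    assert out["bonferroni_factor"] == 2  # 1 condition x 2 SNRs


def test_compare_accuracy_detects_large_separation():
    rng = np.random.default_rng(0)
    rows = [("A", "c1", 0, x) for x in rng.normal(0.5, 0.01, 50)]
    rows += [("B", "c1", 0, x) for x in rng.normal(0.9, 0.01, 50)]
    rows += [("A", "c2", 0, 0.5), ("A", "c2", 0, 0.5),
             ("B", "c2", 0, 0.5), ("B", "c2", 0, 0.5)]
    out = compare_accuracy(_scores_frame(rows))
    tests = out["tests"]
    cell = tests[(tests.condition == "c1")]
    assert bool(cell["significant"].iloc[0])
    assert out["bonferroni_factor"] == 2
    assert cell["p_bonferroni"].iloc[0] == pytest.approx(
        min(1.0, cell["p"].iloc[0] * 2))


def test_compare_free_energy_fixed_effects_summary():
    F = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
    out = compare_free_energy(F)
    row = out.iloc[0]
    assert row["mean_dF"] == 0.0 and row["fraction_favoring_a"] == 0.5
    F2 = pd.DataFrame({"A": [4.0, 5.0, 6.0], "B": [1.0, 2.0, 3.0]})
    row2 = compare_free_energy(F2).iloc[0]
    assert row2["fraction_favoring_a"] == 1.0 and row2["mean_dF"] == 3.0
    # incomplete rows dropped with a log entry
    logs = []
    F3 = pd.DataFrame({"A": [1.0, np.nan], "B": [0.0, 1.0]})
    out3 = compare_free_energy(F3, log=logs.append)
    assert out3.iloc[0]["n"] == 1 and logs


def test_free_energy_prefers_ard_over_ebb_at_low_snr(
        small_head, small_leadfield, small_centers, small_locations,
        small_projector, small_library):
    """At -20 dB the adaptive patch prior explains the data better than the
    beamformer prior in most simulations (fixed-effects comparison)."""
    mesh, _ = small_head
    rows = []
    for seed in range(5):
        ds, model = make_model(mesh, small_leadfield, small_centers,
                               small_locations, small_projector,
                               snr_db=-20.0, seed=40 + seed, n_trials=60)
        rows.append({"ARD": invert(model, "ARD", library=small_library).F_final,
                     "EBB": invert(model, "EBB").F_final})
    out = compare_free_energy(pd.DataFrame(rows))
    row = out.iloc[0]
    assert row["fraction_favoring_a" if row["scheme_a"] == "ARD"
               else "fraction_favoring_a"] is not None
    frac_ard = (row["fraction_favoring_a"] if row["scheme_a"] == "ARD"
                else 1.0 - row["fraction_favoring_a"])
    assert frac_ard > 0.5
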