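"""Geometry, forward-model and patch-smoother correctness."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from megbayes import build_synthetic_head, compute_leadfield, green_smoother, select_patch_centers
from megbayes.geometry_forward import GeometryError, mirror_pairs, sarvas_field

MU0_4PI = 1e-7


# ---------------------------------------------------------------------------
# synthetic head
# ---------------------------------------------------------------------------


def test_default_head_matches_cortical_scale():
    """~8k-vertex default head has a ~5 mm mean edge (cortex-like density)."""
    mesh, sensors = build_synthetic_head(n_vertices=8196, seed=1)
    assert abs(mesh.mean_edge_mm - 5.0) <= 1.0  # within 20%
    radii = np.linalg.norm(mesh.vertices, axis=1)
    assert radii.max() < sensors.conductor_radius_mm
    assert np.allclose(np.linalg.norm(mesh.normals, axis=1), 1.0, atol=1e-9)


def test_icosahedron_has_radial_unit_normals():
    mesh, _ = build_synthetic_head(n_vertices=12, wrinkle_amp_mm=0.0, seed=0)
    assert mesh.n_vertices == 12
    rhat = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    assert np.allclose(np.abs(np.einsum("ij,ij->i", mesh.normals, rhat)), 1.0,
                       atol=1e-9)


def test_head_determinism_and_seed_sensitivity():
    a, _ = build_synthetic_head(n_vertices=162, seed=5)
    b, _ = build_synthetic_head(n_vertices=162, seed=5)
    c, _ = build_synthetic_head(n_vertices=162, seed=6)
    assert np.array_equal(a.vertices, b.vertices)
    assert not np.array_equal(a.vertices, c.vertices)


def test_head_parameter_validation():
    with pytest.raises(ValueError):
        build_synthetic_head(n_vertices=5)
    with pytest.raises(ValueError):
        build_synthetic_head(cortex_radius_mm=100, conductor_radius_mm=90)
    with pytest.raises(ValueError):
        build_synthetic_head(n_sensors=4)


def test_hemispheres_connected_and_sensors_outside(small_head):
    mesh, sensors = small_head
    for hemi in (0, 1):
        verts = mesh.vertices_of(hemi)
        sub = mesh.adjacency[np.ix_(verts, verts)]
        ncomp, _ = connected_components(sub, directed=False)
        assert ncomp == 1
    assert np.all(np.linalg.norm(sensors.positions, axis=1)
                  > sensors.conductor_radius_mm)
    assert np.allclose(np.linalg.norm(sensors.orientations, axis=1), 1.0)


# ---------------------------------------------------------------------------
# single-sphere forward model
# ---------------------------------------------------------------------------


def _scalar_potential(r_mm, r0_mm, q_nAm):
    r = r_mm * 1e-3
    r0 = r0_mm * 1e-3
    q = q_nAm * 1e-9
    a = r - r0
    na = np.sqrt(a @ a)
    nr = np.sqrt(r @ r)
    F = na * (nr * na + nr**2 - r0 @ r)
    return -(np.cross(q, r0) @ r) / (4.0 * np.pi * F)


def test_field_matches_potential_gradient_oracle():
    """B equals -mu0 grad(U) of the magnetic scalar potential (numerically)."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        r0 = rng.uniform(-40, 40, 3)
        q = np.cross(r0, rng.normal(size=3))
        q /= np.linalg.norm(q)
        sens = rng.normal(size=3)
        sens *= rng.uniform(110, 140) / np.linalg.norm(sens)
        B = sarvas_field(r0[None], q[None], sens[None])[0, 0]
        h = 1e-4
        grad = np.zeros(3)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            grad[k] = (_scalar_potential(sens + e, r0, q)
                       - _scalar_potential(sens - e, r0, q)) / (2 * h * 1e-3)
        B_num = -4 * np.pi * MU0_4PI * grad * 1e15
        assert np.linalg.norm(B - B_num) <= 1e-6 * np.linalg.norm(B)


def test_radial_field_matches_biot_savart_of_primary_current():
    """Volume currents are radially silent: B.r from the primary term only."""
    rng = np.random.default_rng(4)
    for _ in range(5):
        r0 = rng.uniform(-40, 40, 3)
        q = np.cross(r0, rng.normal(size=3))
        q /= np.linalg.norm(q)
        sens = rng.normal(size=3)
        sens *= 120.0 / np.linalg.norm(sens)
        B = sarvas_field(r0[None], q[None], sens[None])[0, 0]
        a = (sens - r0) * 1e-3
        Bp = MU0_4PI * np.cross(q * 1e-9, a) / np.linalg.norm(a) ** 3 * 1e15
        rhat = sens / np.linalg.norm(sens)
        assert abs(B @ rhat - Bp @ rhat) <= 1e-6 * max(abs(Bp @ rhat), 1e-12)


def test_radial_dipoles_are_silent(small_head):
    mesh, _ = small_head
    rng = np.random.default_rng(0)
    idx = rng.choice(mesh.n_vertices, 100, replace=False)
    pos = mesh.vertices[idx]
    radial = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    tang = np.cross(pos, rng.normal(size=pos.shape))
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    sens = np.array([[0.0, 0.0, 120.0], [90.0, 0.0, 90.0]])
    B_rad = sarvas_field(pos, radial, sens)
    B_tan = sarvas_field(pos, tang, sens)
    assert (np.linalg.norm(B_rad) <= 1e-8 * np.linalg.norm(B_tan))


def test_leadfield_linearity_and_superposition(small_head):
    mesh, sensors = small_head
    p = mesh.vertices[[10, 20]]
    q1 = np.cross(p, [[0, 0, 1.0], [0, 1.0, 0]])
    q2 = np.cross(p, [[1.0, 0, 0], [0, 0, 1.0]])
    B1 = sarvas_field(p, q1, sensors.positions)
    B2 = sarvas_field(p, q2, sensors.positions)
    B = sarvas_field(p, 2.0 * q1 + 0.5 * q2, sensors.positions)
    assert np.allclose(B, 2.0 * B1 + 0.5 * B2, rtol=0, atol=1e-12 * np.abs(B).max())


def test_leadfield_geometry_errors(small_head):
    mesh, sensors = small_head
    with pytest.raises(GeometryError):
        sarvas_field(np.zeros((1, 3)), np.ones((1, 3)), sensors.positions)
    inside = sensors
    inside = type(sensors)(positions=mesh.vertices[:2] * 0.5,
                           orientations=np.tile([0, 0, 1.0], (2, 1)),
                           conductor_center=np.zeros(3),
                           conductor_radius_mm=sensors.conductor_radius_mm)
    with pytest.raises(GeometryError):
        compute_leadfield(mesh, inside)


def test_leadfield_gain_finite_and_doubling(small_head, small_leadfield):
    mesh, sensors = small_head
    assert np.all(np.isfinite(small_leadfield.gain))
    doubled = sarvas_field(mesh.vertices[:5], 2.0 * mesh.normals[:5],
                           sensors.positions)
    single = sarvas_field(mesh.vertices[:5], mesh.normals[:5],
                          sensors.positions)
    assert np.allclose(doubled, 2.0 * single, rtol=1e-12)


# ---------------------------------------------------------------------------
# Green smoother
# ---------------------------------------------------------------------------


def test_smoother_zero_smoothness_is_identity(small_head):
    mesh, _ = small_head
    G = green_smoother(mesh, 0.0)
    assert (G.G != sp.identity(mesh.n_vertices, format="csc")).nnz == 0


def _bfs_hops(mesh, center, max_order):
    adj = mesh.adjacency
    dist = {center: 0}
    frontier = [center]
    for d in range(1, max_order + 1):
        nxt = []
        for u in frontier:
            for w in adj.indices[adj.indptr[u]:adj.indptr[u + 1]]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return dist


def test_smoother_support_within_8th_order_bfs_oracle(small_head, small_smoother, small_centers):
    mesh, _ = small_head
    for c in small_centers[:8]:
        col = small_smoother.column(int(c))
        reachable = _bfs_hops(mesh, int(c), 8)
        assert set(np.flatnonzero(col)) <= set(reachable)
        assert col.max() == pytest.approx(1.0)
        assert np.all(col >= 0)


def test_smoother_spread_monotone_in_smoothness(small_head, small_centers):
    mesh, _ = small_head
    c = int(small_centers[0])
    counts = []
    for s in (0.2, 0.4, 0.6, 0.8):
        col = green_smoother(mesh, s, columns=[c]).column(c)
        counts.append(int(np.sum(col > 0.6 * col.max())))
    assert counts == sorted(counts)


def test_smoother_symmetry_where_degrees_equal(small_head):
    mesh, _ = small_head
    deg = np.asarray(mesh.adjacency.sum(axis=1)).ravel()
    regular = np.flatnonzero(deg == 6)
    i, j = int(regular[10]), int(regular[11])
    G = green_smoother(mesh, 0.6, columns=[i, j], rel_floor=0.0)
    gij, gji = G.G[i, j], G.G[j, i]
    # both columns normalized by (numerically equal) maxima
    assert gij == pytest.approx(gji, abs=1e-6)


def test_smoother_rejects_bad_smoothness(small_head):
    mesh, _ = small_head
    with pytest.raises(ValueError):
        green_smoother(mesh, 1.5)


# ---------------------------------------------------------------------------
# patch centres
# ---------------------------------------------------------------------------


def test_patch_center_counts_and_hemispheres(small_head):
    mesh, _ = small_head
    centers = select_patch_centers(mesh, 16, seed=0)
    assert len(centers) == 32
    assert (mesh.hemisphere[centers] == 0).sum() == 16
    assert (mesh.hemisphere[centers] == 1).sum() == 16
    one = select_patch_centers(mesh, 1, seed=0)
    assert len(one) == 2


def test_patch_centers_cover_uniformly(small_head, small_centers):
    """Min pairwise distance at least half the expected uniform spacing."""
    mesh, _ = small_head
    for hemi in (0, 1):
        cs = small_centers[mesh.hemisphere[small_centers] == hemi]
        pos = mesh.vertices[cs]
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        hemi_area = 2 * np.pi * (71.0**2)  # half the cortical sphere
        expected = np.sqrt(hemi_area / len(cs))
        assert d.min() >= 0.5 * expected


def test_patch_centers_deterministic_and_validated(small_head):
    mesh, _ = small_head
    a = select_patch_centers(mesh, 8, seed=3)
    b = select_patch_centers(mesh, 8, seed=3)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        select_patch_centers(mesh, mesh.n_vertices, seed=0)


def test_mirror_pairs_are_contralateral(small_head, small_centers):
    mesh, _ = small_head
    pairs = mirror_pairs(mesh, small_centers)
    assert len(pairs) == 24
    for left, right in pairs:
        assert mesh.hemisphere[left] == 0 and mesh.hemisphere[right] == 1
        refl = mesh.vertices[left] * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(mesh.vertices[right] - refl)
        assert d < 3.5 * mesh.mean_edge_mm
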