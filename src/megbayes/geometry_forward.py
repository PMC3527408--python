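"""Synthetic head geometry and the single-sphere MEG forward model.

The source space is a two-hemisphere "wrinkled sphere": a subdivided
icosahedron whose radius is modulated by a smooth seeded perturbation, so
that vertex normals are not purely radial and the mesh has a cortex-like
surface density.  Sensors form a spherical helmet outside the conducting
sphere.  Leadfields use the closed-form magnetic field of a current dipole
in a homogeneous spherical conductor (Sarvas), with source orientation
fixed along the vertex normal.  Patch priors are built from a graph
Green-function smoother: a truncated matrix exponential of the mesh
adjacency operator.

Units: positions in mm, dipole moments in nAm, fields in fT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "SourceMesh",
    "SensorArray",
    "Leadfield",
    "GreenSmoother",
    "build_synthetic_head",
    "compute_leadfield",
    "sarvas_field",
    "green_smoother",
    "select_patch_centers",
    "mirror_pairs",
]

_MU0_OVER_4PI = 1e-7  # T*m/A

# subdivided-icosahedron vertex counts 10*4^n + 2
_ICO_COUNTS = [10 * 4**n + 2 for n in range(8)]


class GeometryError(ValueError):
    """Raised for inconsistent head geometry (dipole at centre, sensor inside sphere...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SourceMesh:
    """Tessellated source surface.

    vertices : (v, 3) mm, relative to the conductor centre
    faces : (f, 3) int triangles
    normals : (v, 3) unit outward vertex normals (dipole orientations)
    hemisphere : (v,) int8, 0 = left (x < 0), 1 = right
    adjacency : (v, v) sparse boolean first-order neighbour graph
    mean_edge_mm : mean mesh edge length
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    hemisphere: np.ndarray
    adjacency: sp.csr_matrix
    mean_edge_mm: float

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def vertices_of(self, hemi: int) -> np.ndarray:
        """Indices of all vertices in hemisphere ``hemi`` (0 left, 1 right)."""
        return np.flatnonzero(self.hemisphere == hemi)

    def edge_weighted_adjacency(self) -> sp.csr_matrix:
        """Adjacency with Euclidean edge lengths (mm) as weights."""
        a = self.adjacency.tocoo()
        w = np.linalg.norm(self.vertices[a.row] - self.vertices[a.col], axis=1)
        return sp.csr_matrix((w, (a.row, a.col)), shape=a.shape)


@dataclass
class SensorArray:
    """Point magnetometers on a helmet around the conductor sphere."""

    positions: np.ndarray  # (n, 3) mm, relative to conductor centre
    orientations: np.ndarray  # (n, 3) unit vectors
    conductor_center: np.ndarray  # (3,) mm
    conductor_radius_mm: float

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class Leadfield:
    """Gain matrix: field per unit dipole moment, n_sensors x v (fT / nAm)."""

    gain: np.ndarray
    source_orientation_mode: str = "fixed-normal"

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class GreenSmoother:
    """Column-truncated graph Green function G = expm(s * (D^-1 A - I)).

    Columns are truncated to the 8th-order graph neighbourhood of their
    centre vertex and to entries >= 1e-4 of the column maximum, then
    rescaled to unit maximum.  Only the requested columns are populated.
    """

    G: sp.csc_matrix
    s: float
    max_neighbor_order: int = 8
    columns: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def column(self, j: int) -> np.ndarray:
        return np.asarray(self.G[:, j].todense()).ravel()


# ---------------------------------------------------------------------------
# synthetic head
# ---------------------------------------------------------------------------


def _wrinkle_field(unit_vertices: np.ndarray, radius_mm: float,
                   wavelength_mm: float, n_waves: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth pseudo-random radial perturbation: a sum of surface plane waves.

    Returns a zero-mean field with unit RMS over the vertices.
    """
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    k = 2.0 * np.pi * radius_mm / wavelength_mm
    f = np.sin(k * unit_vertices @ dirs.T + phases).sum(axis=1)
    f -= f.mean()
    rms = np.sqrt(np.mean(f**2))
    return f / max(rms, 1e-12)


def _mesh_adjacency(n_vertices: int, faces: np.ndarray) -> sp.csr_matrix:
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2],
                        faces[:, 1], faces[:, 2], faces[:, 0]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0],
                        faces[:, 0], faces[:, 1], faces[:, 2]])
    a = sp.csr_matrix((np.ones_like(i, dtype=float), (i, j)),
                      shape=(n_vertices, n_vertices))
    a.data[:] = 1.0  # collapse duplicate entries
    return a


def build_synthetic_head(
    n_vertices: int = 8196,
    cortex_radius_mm: float = 71.0,
    conductor_radius_mm: float = 95.0,
    n_sensors: int = 275,
    seed: int = 0,
    wrinkle_amp_mm: float = 7.0,
    wrinkle_wavelength_mm: float = 18.0,
    n_waves: int = 8,
) -> tuple[SourceMesh, SensorArray]:
    """Build a seeded two-hemisphere wrinkled-sphere mesh and a sensor helmet.

    The icosphere subdivision level is chosen so the vertex count is the
    closest achievable to ``n_vertices`` (counts are 10*4^n + 2).  The radial
    wrinkle emulates cortical folding: it stretches the surface so that the
    mean edge length approaches the ~5 mm of a real cortical tessellation,
    and it tilts vertex normals away from the radial direction.  Sensors sit
    on a spherical cap of radius 1.3 x conductor radius with tangential
    orientations.  Fully deterministic given ``seed``.
    """
    import trimesh

    if n_vertices < 12:
        raise ValueError(f"n_vertices must be >= 12, got {n_vertices}")
    if not cortex_radius_mm < conductor_radius_mm:
        raise ValueError("cortex_radius_mm must be smaller than conductor_radius_mm")
    if n_sensors < 16:
        raise ValueError(f"n_sensors must be >= 16, got {n_sensors}")
    if wrinkle_amp_mm < 0:
        raise ValueError("wrinkle_amp_mm must be non-negative")

    subdiv = int(np.argmin([abs(c - n_vertices) for c in _ICO_COUNTS]))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)

    rng = np.random.default_rng(seed)
    if wrinkle_amp_mm > 0.0:
        f = _wrinkle_field(unit, cortex_radius_mm, wrinkle_wavelength_mm,
                           n_waves, rng)
        dr = wrinkle_amp_mm * f
        # hard cap so every vertex stays strictly inside the conductor
        cap = 0.95 * conductor_radius_mm - cortex_radius_mm
        dr = np.clip(dr, -0.45 * cortex_radius_mm, cap)
    else:
        rng.normal()  # keep the stream position independent of the branch
        dr = np.zeros(len(unit))

    radii = cortex_radius_mm + dr
    vertices = unit * radii[:, None]
    if np.max(np.linalg.norm(vertices, axis=1)) >= conductor_radius_mm:
        raise GeometryError("wrinkled cortex pierces the conductor sphere")

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    normals = np.asarray(mesh.vertex_normals, dtype=float).copy()
    # trimesh normals point outward for this construction; normalize exactly
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    hemisphere = (vertices[:, 0] >= 0).astype(np.int8)
    adjacency = _mesh_adjacency(len(vertices), faces)

    edges = mesh.edges_unique
    edge_len = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)
    mean_edge = float(edge_len.mean())

    source_mesh = SourceMesh(vertices=vertices, faces=faces, normals=normals,
                             hemisphere=hemisphere, adjacency=adjacency,
                             mean_edge_mm=mean_edge)

    sensors = _build_helmet(n_sensors, conductor_radius_mm, rng)
    return source_mesh, sensors


def _build_helmet(n_sensors: int, conductor_radius_mm: float,
                  rng: np.random.Generator) -> SensorArray:
    """Fibonacci-lattice cap of tangential point magnetometers."""
    helmet_r = 1.3 * conductor_radius_mm
    # spherical cap covering z > -0.35 (most of the head, like a MEG helmet)
    z_lo = -0.35
    idx = np.arange(n_sensors, dtype=float)
    z = 1.0 - (1.0 - z_lo) * (idx + 0.5) / n_sensors
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * idx
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    # seeded random rotation about z so different seeds give distinct helmets
    ang = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                    [np.sin(ang), np.cos(ang), 0.0],
                    [0.0, 0.0, 1.0]])
    pts = pts @ rot.T
    positions = helmet_r * pts

    # tangential orientation: azimuthal direction, polar fallback at the pole
    zhat = np.array([0.0, 0.0, 1.0])
    orient = np.cross(np.broadcast_to(zhat, pts.shape), pts)
    nrm = np.linalg.norm(orient, axis=1)
    polar = np.abs(nrm) < 1e-8
    if polar.any():
        orient[polar] = np.cross(np.array([1.0, 0.0, 0.0]), pts[polar])
        nrm = np.linalg.norm(orient, axis=1)
    orient /= nrm[:, None]

    return SensorArray(positions=positions, orientations=orient,
                       conductor_center=np.zeros(3),
                       conductor_radius_mm=float(conductor_radius_mm))


# ---------------------------------------------------------------------------
# single-sphere forward model
# ---------------------------------------------------------------------------


def sarvas_field(dipole_pos_mm: np.ndarray, dipole_moment_nAm: np.ndarray,
                 sensor_pos_mm: np.ndarray) -> np.ndarray:
    """Magnetic field (fT) of current dipoles in a homogeneous sphere.

    Closed-form solution for a spherically symmetric conductor centred at
    the origin: volume currents are accounted for analytically and radial
    dipoles are exactly silent.

    Parameters
    ----------
    dipole_pos_mm : (v, 3) dipole positions (mm, relative to sphere centre)
    dipole_moment_nAm : (v, 3) dipole moments (nAm)
    sensor_pos_mm : (n, 3) field points (mm, outside the sphere)

    Returns
    -------
    (n, v, 3) field vectors in fT.
    """
    r0 = np.atleast_2d(dipole_pos_mm) * 1e-3  # m
    q = np.atleast_2d(dipole_moment_nAm) * 1e-9  # A*m
    r = np.atleast_2d(sensor_pos_mm) * 1e-3  # m

    if np.any(np.linalg.norm(r0, axis=1) < 1e-9):
        raise GeometryError("dipole at the sphere centre has no defined field")

    a_vec = r[:, None, :] - r0[None, :, :]  # (n, v, 3)
    a = np.linalg.norm(a_vec, axis=2)  # (n, v)
    if np.any(a < 1e-9):
        raise GeometryError("field point coincides with a dipole")
    rn = np.linalg.norm(r, axis=1)[:, None]  # (n, 1)
    r0_dot_r = r @ r0.T  # (n, v)
    a_dot_r = np.einsum("nvk,nk->nv", a_vec, r)

    F = a * (rn * a + rn**2 - r0_dot_r)
    coef_r = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
    coef_r0 = a + 2.0 * rn + a_dot_r / a
    gradF = coef_r[:, :, None] * r[:, None, :] - coef_r0[:, :, None] * r0[None, :, :]

    q_x_r0 = np.cross(q, r0)  # (v, 3)
    qxr0_dot_r = r @ q_x_r0.T  # (n, v)

    B = (_MU0_OVER_4PI / F[:, :, None] ** 2) * (
        F[:, :, None] * q_x_r0[None, :, :] - qxr0_dot_r[:, :, None] * gradF
    )
    return B * 1e15  # fT


def compute_leadfield(mesh: SourceMesh, sensors: SensorArray) -> Leadfield:
    """Single-sphere leadfield for unit dipoles along the vertex normals.

    gain[i, j] is the field (fT) along sensor orientation i produced by a
    1 nAm dipole at vertex j oriented along its surface normal.
    """
    center = sensors.conductor_center
    src = mesh.vertices - center
    sens = sensors.positions - center
    if np.any(np.linalg.norm(sens, axis=1) <= sensors.conductor_radius_mm):
        raise GeometryError("sensor inside the conductor sphere")
    if np.any(np.linalg.norm(src, axis=1) >= sensors.conductor_radius_mm):
        raise GeometryError("source vertex outside the conductor sphere")

    B = sarvas_field(src, mesh.normals, sens)  # (n, v, 3)
    gain = np.einsum("nvk,nk->nv", B, sensors.orientations)
    if not np.all(np.isfinite(gain)):
        raise GeometryError("non-finite leadfield")
    return Leadfield(gain=gain)


# ---------------------------------------------------------------------------
# Green-function patch smoother
# ---------------------------------------------------------------------------


def _neighborhood(adj_indptr, adj_indices, center: int, order: int):
    """Vertices within ``order`` hops of ``center`` and their hop distance."""
    dist = {center: 0}
    frontier = [center]
    for d in range(1, order + 1):
        nxt = []
        for u in frontier:
            for w in adj_indices[adj_indptr[u]:adj_indptr[u + 1]]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
        if not frontier:
            break
    nodes = np.fromiter(dist.keys(), dtype=np.int64)
    hops = np.fromiter(dist.values(), dtype=np.int64)
    return nodes, hops


def green_smoother(mesh: SourceMesh, s: float,
                   columns: np.ndarray | None = None,
                   max_neighbor_order: int = 8,
                   rel_floor: float = 1e-4,
                   rate_scale: float = 6.0,
                   ref_edge_mm: float = 5.0) -> GreenSmoother:
    """Graph Green-function smoother, a diffusion kernel on the mesh graph.

    G = expm(tau * (D^-1 A - I)) with diffusion time
    tau = rate_scale * s * (ref_edge_mm / mean_edge_mm)^2.  ``rate_scale``
    of 6 (the mean vertex degree of a triangulated sphere) makes the
    operator equivalent to expm(s (A - D)) on a regular 5 mm mesh — unit
    per-neighbour rate per unit s — which at s = 0.6 yields roughly 10 mm
    of local coherence.  The (ref_edge/mean_edge)^2 factor keeps the patch
    extent fixed in millimetres rather than in hops, so coarser synthetic
    meshes carry patches of the same physical size.

    Each column is computed exactly on the local subgraph two hops beyond
    the support cap, truncated to ``max_neighbor_order``-hop support and to
    entries >= ``rel_floor`` of the column maximum, then rescaled to unit
    maximum.  ``s = 0`` gives the identity.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"smoothness s must be in [0, 1], got {s}")
    v = mesh.n_vertices
    n_comp, _ = connected_components(mesh.adjacency, directed=False)
    if n_comp != 1:
        raise ValueError("mesh adjacency graph is disconnected")

    tau = rate_scale * s * (ref_edge_mm / mesh.mean_edge_mm) ** 2
    if columns is None:
        columns = np.arange(v)
    columns = np.asarray(columns, dtype=np.int64)

    adj = mesh.adjacency.tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()

    data, rows, cols = [], [], []
    for c in columns:
        if s == 0.0:
            data.append(np.array([1.0]))
            rows.append(np.array([c]))
            cols.append(np.array([c]))
            continue
        nodes, hops = _neighborhood(adj.indptr, adj.indices, int(c),
                                    max_neighbor_order + 2)
        local = {int(n): i for i, n in enumerate(nodes)}
        sub = adj[np.ix_(nodes, nodes)].tocoo()
        # row-normalize with the FULL-graph degrees, then subtract identity
        w = sub.data / deg[nodes[sub.row]]
        gl = sp.csr_matrix((w, (sub.row, sub.col)), shape=(len(nodes),) * 2)
        gl = gl - sp.identity(len(nodes), format="csr")
        e = np.zeros(len(nodes))
        e[local[int(c)]] = 1.0
        x = expm_multiply(tau * gl, e)
        x[hops > max_neighbor_order] = 0.0
        x = np.maximum(x, 0.0)
        m = x.max()
        x[x < rel_floor * m] = 0.0
        x /= m
        nz = np.flatnonzero(x)
        data.append(x[nz])
        rows.append(nodes[nz])
        cols.append(np.full(len(nz), c, dtype=np.int64))

    G = sp.csc_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(v, v),
    )
    return GreenSmoother(G=G, s=float(s), max_neighbor_order=max_neighbor_order,
                         columns=columns)


# ---------------------------------------------------------------------------
# patch centres
# ---------------------------------------------------------------------------


def select_patch_centers(mesh: SourceMesh, p_per_hemisphere: int,
                         seed: int = 0) -> np.ndarray:
    """Farthest-point sampling of patch centres, per hemisphere.

    Greedy max-min sampling under graph-geodesic distance (Euclidean edge
    weights) gives approximately uniform coverage; the first centre of each
    hemisphere is drawn with ``seed``.  Returns the concatenated left then
    right centres (p each).
    """
    rng = np.random.default_rng(seed)
    wadj = mesh.edge_weighted_adjacency()
    all_centers = []
    for hemi in (0, 1):
        verts = mesh.vertices_of(hemi)
        if p_per_hemisphere > len(verts):
            raise ValueError(
                f"p_per_hemisphere={p_per_hemisphere} exceeds the "
                f"{len(verts)} vertices of hemisphere {hemi}")
        sub = wadj[np.ix_(verts, verts)]
        start = int(rng.integers(len(verts)))
        chosen = [start]
        mind = dijkstra(sub, directed=False, indices=start)
        for _ in range(1, p_per_hemisphere):
            nxt = int(np.argmax(np.where(np.isinf(mind), -1.0, mind)))
            chosen.append(nxt)
            d = dijkstra(sub, directed=False, indices=nxt)
            mind = np.minimum(mind, d)
        all_centers.append(verts[np.asarray(chosen)])
    return np.concatenate(all_centers)


def mirror_pairs(mesh: SourceMesh, centers: np.ndarray,
                 max_pair_dist_mm: float | None = None) -> list[tuple[int, int]]:
    """Pair each left-hemisphere centre with its mirror-hemisphere twin.

    The twin is the right-hemisphere centre nearest to the reflection of the
    left centre across the mid-sagittal plane (x -> -x).  Raises if the
    nearest candidate is farther than ``max_pair_dist_mm`` (default: 4 x the
    median nearest-centre spacing).
    """
    centers = np.asarray(centers)
    left = centers[mesh.hemisphere[centers] == 0]
    right = centers[mesh.hemisphere[centers] == 1]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("centers must include both hemispheres")
    rpos = mesh.vertices[right]
    if max_pair_dist_mm is None:
        from scipy.spatial import cKDTree
        tree = cKDTree(rpos)
        d, _ = tree.query(rpos, k=min(2, len(rpos)))
        spacing = np.median(d[:, -1]) if len(rpos) > 1 else np.inf
        max_pair_dist_mm = 4.0 * spacing
    pairs = []
    for c in left:
        refl = mesh.vertices[c] * np.array([-1.0, 1.0, 1.0])
        d = np.linalg.norm(rpos - refl, axis=1)
        j = int(np.argmin(d))
        if d[j] > max_pair_dist_mm:
            raise ValueError(
                f"no contralateral partner for centre {int(c)}: nearest "
                f"candidate is {d[j]:.1f} mm from the mirror point")
        pairs.append((int(c), int(right[j])))
    return pairs
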