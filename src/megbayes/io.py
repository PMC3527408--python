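"""Serialization: meshes (OFF/PLY), leadfields and epochs (HDF5 + TSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .geometry_forward import Leadfield, SensorArray, SourceMesh

__all__ = [
    "save_mesh", "save_head", "load_head",
    "save_leadfield", "load_leadfield",
    "save_epochs", "load_epochs",
    "write_tsv",
]


def save_mesh(mesh: SourceMesh, path: str | Path) -> Path:
    """Export the surface as ASCII OFF or PLY (by file extension)."""
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    kind = path.suffix.lstrip(".").lower()
    if kind not in ("off", "ply"):
        raise ValueError(f"unsupported mesh format {kind!r} (use off/ply)")
    data = trimesh.exchange.export.export_mesh(
        tm, None, file_type=kind,
        **({"encoding": "ascii"} if kind == "ply" else {}))
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def save_head(mesh: SourceMesh, sensors: SensorArray, out_dir: str | Path) -> Path:
    import h5py

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_dir / "head.h5", "w") as f:
        g = f.create_group("mesh")
        g.create_dataset("vertices", data=mesh.vertices)
        g.create_dataset("faces", data=mesh.faces)
        g.create_dataset("normals", data=mesh.normals)
        g.create_dataset("hemisphere", data=mesh.hemisphere)
        g.attrs["mean_edge_mm"] = mesh.mean_edge_mm
        s = f.create_group("sensors")
        s.create_dataset("positions", data=sensors.positions)
        s.create_dataset("orientations", data=sensors.orientations)
        s.create_dataset("conductor_center", data=sensors.conductor_center)
        s.attrs["conductor_radius_mm"] = sensors.conductor_radius_mm
    save_mesh(mesh, out_dir / "cortex.off")
    return out_dir / "head.h5"


def load_head(path: str | Path) -> tuple[SourceMesh, SensorArray]:
    import h5py

    from .geometry_forward import _mesh_adjacency

    path = Path(path)
    if path.is_dir():
        path = path / "head.h5"
    with h5py.File(path, "r") as f:
        g, s = f["mesh"], f["sensors"]
        vertices = g["vertices"][()]
        faces = g["faces"][()]
        mesh = SourceMesh(
            vertices=vertices, faces=faces, normals=g["normals"][()],
            hemisphere=g["hemisphere"][()],
            adjacency=_mesh_adjacency(len(vertices), faces),
            mean_edge_mm=float(g.attrs["mean_edge_mm"]))
        sensors = SensorArray(
            positions=s["positions"][()], orientations=s["orientations"][()],
            conductor_center=s["conductor_center"][()],
            conductor_radius_mm=float(s.attrs["conductor_radius_mm"]))
    return mesh, sensors


def save_leadfield(L: Leadfield, path: str | Path, tsv: bool = False) -> Path:
    path = Path(path)
    if tsv or path.suffix == ".tsv":
        np.savetxt(path, L.gain, delimiter="\t")
        return path
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("gain", data=L.gain)
        d.attrs["source_orientation_mode"] = L.source_orientation_mode
        d.attrs["units"] = "fT per nAm"
    return path


def load_leadfield(path: str | Path) -> Leadfield:
    path = Path(path)
    if path.suffix == ".tsv":
        return Leadfield(gain=np.loadtxt(path, delimiter="\t"))
    import h5py

    with h5py.File(path, "r") as f:
        return Leadfield(gain=f["gain"][()],
                         source_orientation_mode=str(
                             f["gain"].attrs["source_orientation_mode"]))


def save_epochs(epochs: np.ndarray, path: str | Path, fs_hz: float,
                meta: dict | None = None) -> Path:
    """Trials x sensors x samples container with a JSON sidecar."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=np.asarray(epochs))
        f.attrs["fs_hz"] = fs_hz
    sidecar = dict(meta or {})
    sidecar["fs_hz"] = fs_hz
    sidecar["shape"] = list(np.asarray(epochs).shape)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=_jsonable)
    return path


def load_epochs(path: str | Path) -> tuple[np.ndarray, dict]:
    import h5py

    path = Path(path)
    with h5py.File(path, "r") as f:
        epochs = f["epochs"][()]
        fs = float(f.attrs["fs_hz"])
    meta = {"fs_hz": fs}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta.update(json.load(fh))
    return epochs, meta


def write_tsv(df, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if sp.issparse(x):
        return None
    raise TypeError(f"not JSON-serializable: {type(x)}")
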