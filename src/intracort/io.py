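"""Format adapters: surfaces, parcellations, vertex maps, tables, configs.

CSV is the canonical tabular interchange; PLY is the portable mesh format;
FreeSurfer binary surfaces and annot files are supported read-only for
interoperability.  NIfTI I/O lives on the volume classes themselves.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .surfaces import CorticalSurfacePair, Parcellation, VertexScalarMap

__all__ = [
    "write_surface_ply",
    "read_surface_ply",
    "read_freesurfer_surface",
    "read_freesurfer_annot",
    "write_parcellation_csv",
    "read_parcellation_csv",
    "write_vertex_map_csv",
    "read_vertex_map_csv",
    "write_surface_pair",
    "read_surface_pair",
    "load_config",
    "config_hash",
]


def write_surface_ply(path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    mesh = trimesh.Trimesh(vertices=vertices, faces=triangles, process=False)
    mesh.export(str(path), file_type="ply", encoding="ascii")


def read_surface_ply(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


def read_freesurfer_surface(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a FreeSurfer binary surface (lh.white etc.); coordinates in mm."""
    from nibabel.freesurfer import read_geometry

    verts, faces = read_geometry(str(path))
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def read_freesurfer_annot(path) -> Parcellation:
    """Read a FreeSurfer .annot parcellation into vertex labels + names."""
    from nibabel.freesurfer import read_annot

    labels, _, names = read_annot(str(path))
    labels = np.asarray(labels, dtype=np.int64)
    labels[labels < 0] = 0
    name_map = {i: n.decode() if isinstance(n, bytes) else str(n) for i, n in enumerate(names)}
    present = np.unique(labels)
    return Parcellation(labels, {int(i): name_map.get(int(i), f"region_{i}") for i in present})


def write_parcellation_csv(path, parcellation: Parcellation) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(len(parcellation.labels)),
            "region_id": parcellation.labels,
            "region_name": [parcellation.names[int(r)] for r in parcellation.labels],
        }
    )
    df.to_csv(path, index=False)


def read_parcellation_csv(path) -> Parcellation:
    df = pd.read_csv(path)
    df = df.sort_values("vertex_id")
    names = (
        df.drop_duplicates("region_id").set_index("region_id")["region_name"].to_dict()
        if "region_name" in df.columns
        else {}
    )
    return Parcellation(df["region_id"].to_numpy(), {int(k): str(v) for k, v in names.items()})


def write_vertex_map_csv(path, vmap: VertexScalarMap) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(len(vmap.values)),
            "value": np.where(vmap.missing, np.nan, vmap.values),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_vertex_map_csv(path) -> VertexScalarMap:
    df = pd.read_csv(path).sort_values("vertex_id")
    vals = df["value"].to_numpy(dtype=float)
    return VertexScalarMap(vals, ~np.isfinite(vals))


def write_surface_pair(directory, surfaces: CorticalSurfacePair, prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surface_ply(directory / f"{prefix}white.ply", surfaces.white_vertices, surfaces.triangles)
    write_surface_ply(directory / f"{prefix}pial.ply", surfaces.pial_vertices, surfaces.triangles)


def read_surface_pair(directory, prefix: str = "") -> CorticalSurfacePair:
    directory = Path(directory)
    wv, wf = read_surface_ply(directory / f"{prefix}white.ply")
    pv, pf = read_surface_ply(directory / f"{prefix}pial.ply")
    if not np.array_equal(wf, pf):
        raise ValueError("white and pial surfaces have different triangulations")
    return CorticalSurfacePair(wv, pv, wf)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
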