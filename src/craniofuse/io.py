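"""Surface, landmark, configuration and report I/O.

Surfaces (PLY/OBJ/STL, coordinates in mm) are read through trimesh; mesh
inputs contribute their (deduplicated) vertices and any vertex normals.
Point clouds are written as ASCII PLY, optionally with per-vertex colors, so
error-field exports open in any mesh viewer. Landmarks travel as JSON
(canonical face-mesh index → [x, y, z]); pipeline configuration as
YAML/TOML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import trimesh
import yaml

from .exceptions import InvalidInputError
from .geometry import PointCloud

__all__ = [
    "read_surface",
    "write_point_cloud_ply",
    "read_landmarks_json",
    "write_landmarks_json",
    "load_config_file",
]

_SUPPORTED = {".ply", ".obj", ".stl"}


def read_surface(path: str | Path) -> PointCloud:
    """Load a surface file into a point cloud (mm units assumed).

    Triangle meshes contribute their vertices (shared vertices merged, so an
    STL's per-facet triangle soup deduplicates); raw point-cloud PLYs load
    as-is. Vertex normals are kept when the file provides them.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"surface file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED:
        raise InvalidInputError(f"unsupported surface format {path.suffix!r} (PLY/OBJ/STL)")
    try:
        loaded = trimesh.load(str(path), process=False)
    except Exception as exc:  # parse failure -> typed error
        raise InvalidInputError(f"could not parse {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise InvalidInputError(f"{path} contains no geometry")
        loaded = trimesh.util.concatenate(geoms) if len(geoms) > 1 else geoms[0]
    if isinstance(loaded, trimesh.Trimesh):
        loaded.merge_vertices()
        points = np.asarray(loaded.vertices, dtype=np.float64)
        normals = None
        if loaded.vertex_normals is not None and len(loaded.vertex_normals) == len(points):
            n = np.asarray(loaded.vertex_normals, dtype=np.float64)
            norms = np.linalg.norm(n, axis=1)
            if np.all(norms > 0):
                normals = n / norms[:, None]
        colors = None
    elif isinstance(loaded, trimesh.PointCloud):
        points = np.asarray(loaded.vertices, dtype=np.float64)
        normals = None
        colors = None
        if loaded.colors is not None and len(loaded.colors) == len(points):
            colors = np.asarray(loaded.colors, dtype=np.float64)[:, :3] / 255.0
    else:
        raise InvalidInputError(f"{path} did not load as a mesh or point cloud")
    if points.shape[0] == 0:
        raise InvalidInputError(f"{path} contains no vertices")
    if not np.isfinite(points).all():
        raise InvalidInputError(f"{path} contains non-finite vertices")
    return PointCloud(points, normals=normals, colors=colors)


def write_point_cloud_ply(cloud: PointCloud, path: str | Path) -> None:
    """Write an ASCII PLY with optional per-vertex color and normals."""
    path = Path(path)
    n = len(cloud)
    has_c, has_n = cloud.colors is not None, cloud.normals is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_n:
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
        if has_c:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        cols = [cloud.points]
        if has_n:
            cols.append(cloud.normals)
        data = np.hstack(cols)
        if has_c:
            rgb = np.clip(np.round(cloud.colors * 255.0), 0, 255).astype(int)
            for row, c in zip(data, rgb):
                fh.write(" ".join(f"{v:.6f}" for v in row) + f" {c[0]} {c[1]} {c[2]}\n")
        else:
            for row in data:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_landmarks_json(path: str | Path) -> dict[int, np.ndarray]:
    """JSON {index: [x, y, z]} → landmark dict (cloud-frame mm coordinates)."""
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for k, v in raw.items():
        arr = np.asarray(v, dtype=np.float64)
        if arr.shape != (3,) or not np.isfinite(arr).all():
            raise InvalidInputError(f"landmark {k} must be a finite 3-vector")
        out[int(k)] = arr
    return out


def write_landmarks_json(landmarks: Mapping[int, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): np.asarray(v).tolist() for k, v in landmarks.items()}, fh, indent=1)


def load_config_file(path: str | Path) -> dict:
    """YAML or TOML pipeline configuration → flat dict of overrides."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    return data
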