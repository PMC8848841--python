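"""Readers and writers for the on-disk exchange formats.

Meshes travel as binary little-endian PLY or binary STL (via trimesh),
landmarks as a CSV with columns frame,landmark_id,x,y,z (mm), ground truth
and aspect definitions as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .humerus_frame import AspectCircle
from .synthetic_data import GroundTruth

MESH_SUFFIXES = (".ply", ".stl")


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    path.write_bytes(mesh.export(file_type=path.suffix.lstrip(".").lower()))
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    path = Path(path)
    mesh = trimesh.load_mesh(path, process=False)
    if not isinstance(mesh, trimesh.Trimesh):  # pragma: no cover - scene files
        raise ValueError(f"{path} did not contain a single triangle mesh")
    return mesh


def write_landmarks(path: str | Path, landmarks_per_frame: Sequence[np.ndarray]) -> Path:
    rows = []
    for frame, pts in enumerate(landmarks_per_frame):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        for lm_id, (x, y, z) in enumerate(pts):
            rows.append({"frame": frame, "landmark_id": lm_id, "x": x, "y": y, "z": z})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_landmarks(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    required = {"frame", "landmark_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    out: dict[int, np.ndarray] = {}
    for frame, grp in df.groupby("frame"):
        grp = grp.sort_values("landmark_id")
        out[int(frame)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return out


def _aspect_to_dict(aspect: AspectCircle) -> dict:
    return {
        "center": aspect.center.tolist(),
        "radius": float(aspect.radius),
        "normal": aspect.normal.tolist(),
    }


def _aspect_from_dict(d: dict, side: str) -> AspectCircle:
    return AspectCircle(
        side=side,
        center=np.asarray(d["center"], dtype=float),
        radius=float(d["radius"]),
        normal=np.asarray(d["normal"], dtype=float),
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    payload = {
        "frames": [
            {
                "flexion_deg": float(truth.flexion_deg[i]),
                "axis_point": truth.axis_points[i].tolist(),
                "axis_dir": truth.axis_dirs[i].tolist(),
            }
            for i in range(truth.n_frames)
        ],
    }
    if truth.medial_aspect is not None:
        payload["medial_aspect"] = _aspect_to_dict(truth.medial_aspect)
    if truth.lateral_aspect is not None:
        payload["lateral_aspect"] = _aspect_to_dict(truth.lateral_aspect)
    if truth.shaft_dir is not None:
        payload["shaft_dir"] = np.asarray(truth.shaft_dir, dtype=float).tolist()
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    frames = payload["frames"]
    dirs = np.asarray([f["axis_dir"] for f in frames], dtype=float)
    # re-normalize: JSON round-trip keeps full float precision but guard anyway
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return GroundTruth(
        flexion_deg=np.asarray([f["flexion_deg"] for f in frames], dtype=float),
        axis_points=np.asarray([f["axis_point"] for f in frames], dtype=float),
        axis_dirs=dirs,
        medial_aspect=(
            _aspect_from_dict(payload["medial_aspect"], "medial")
            if "medial_aspect" in payload
            else None
        ),
        lateral_aspect=(
            _aspect_from_dict(payload["lateral_aspect"], "lateral")
            if "lateral_aspect" in payload
            else None
        ),
        shaft_dir=(
            np.asarray(payload["shaft_dir"], dtype=float) if "shaft_dir" in payload else None
        ),
    )


def read_aspects(path: str | Path) -> dict:
    """Aspect sidecar: rim point samples, shaft direction, posterior hint."""
    payload = json.loads(Path(path).read_text())
    out = {
        "medial_rim": np.asarray(payload["medial_rim"], dtype=float),
        "lateral_rim": np.asarray(payload["lateral_rim"], dtype=float),
        "shaft_dir": np.asarray(payload["shaft_dir"], dtype=float),
        "posterior_hint": np.asarray(payload.get("posterior_hint", [0.0, 0.0, 1.0]), dtype=float),
    }
    return out
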