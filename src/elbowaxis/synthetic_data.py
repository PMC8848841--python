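"""Parametric synthetic elbow with a known ground-truth rotation axis.

The generator builds a stylized distal humerus (a frustum whose end caps
are the medial and lateral epicondylar aspect circles) and a proximal ulna
whose greater sigmoid notch is an exact cylindrical arc, then rigidly poses
the ulna through a flexion sequence about a per-frame true axis.  Because
every quantity the downstream estimators recover (notch radius, axis
direction and location, aspect circles, flexion angles) is emitted exactly,
every pipeline stage is testable by parameter recovery.

World conventions (right elbow): X medial->lateral (transcondylar),
Y superior along the humeral shaft, Z posterior.  The medial aspect circle
sits at the origin and the reference notch axis is the X axis, so at zero
drift the true rotation axis coincides with the transcondylar axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import trimesh

from ._geometry import (
    align_vector_rotation,
    apply_transform,
    make_transform,
    rigid_about_line,
    unit,
)
from .humerus_frame import AspectCircle

__all__ = [
    "ElbowParams",
    "AxisTrajectory",
    "GroundTruth",
    "UlnaGeometry",
    "ImageVolume",
    "make_distal_humerus",
    "make_proximal_ulna",
    "pose_sequence",
    "add_vertex_noise",
    "jitter_landmarks",
    "voxelize",
    "write_fixture",
    "fixed_axis_trajectory",
    "drifting_axis_trajectory",
    "sample_aspect_rim",
    "DEFAULT_ROM_DEG",
    "DEFAULT_N_FRAMES",
]

# Mean range of motion of the study cohort and the ~1 s/pose frame count
# of a 30 s acquisition; used as the default synthetic sequence.
DEFAULT_ROM_DEG = 106.5
DEFAULT_N_FRAMES = 30


@dataclass(frozen=True)
class ElbowParams:
    """Geometric parameters of the stylized elbow (all in mm / deg)."""

    notch_radius: float = 12.0
    notch_width: float = 20.0
    notch_arc: float = 170.0
    notch_wall_thickness: float = 6.0
    medial_aspect_radius: float = 10.0
    lateral_aspect_radius: float = 8.0
    transcondylar_length: float = 50.0
    mesh_resolution: float = 1.0

    def __post_init__(self) -> None:
        lengths = {
            "notch_radius": self.notch_radius,
            "notch_width": self.notch_width,
            "notch_wall_thickness": self.notch_wall_thickness,
            "medial_aspect_radius": self.medial_aspect_radius,
            "lateral_aspect_radius": self.lateral_aspect_radius,
            "transcondylar_length": self.transcondylar_length,
            "mesh_resolution": self.mesh_resolution,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 < self.notch_arc < 360:
            raise ValueError(f"notch_arc must be in (0, 360), got {self.notch_arc}")
        if self.mesh_resolution >= self.notch_radius / 4:
            raise ValueError("mesh_resolution must be finer than notch_radius / 4")


@dataclass(frozen=True)
class AxisTrajectory:
    """Per-frame true rotation axis of the posed sequence.

    Drift functions take the flexion angle (deg) and return the signed tilt
    (deg) of the axis away from the transcondylar X axis in the coronal
    (XY) and horizontal (XZ) planes; the point offset function returns the
    axis point (mm, humerus coordinates, on the medial aspect plane).
    """

    flexion_angles: np.ndarray
    coronal_drift: Callable[[float], float]
    horizontal_drift: Callable[[float], float]
    axis_point_offset: Callable[[float], np.ndarray]

    def __post_init__(self) -> None:
        angles = np.asarray(self.flexion_angles, dtype=float)
        if angles.ndim != 1 or len(angles) == 0:
            raise ValueError("flexion_angles must be a non-empty 1-D sequence")
        if len(angles) > 1 and not np.all(np.diff(angles) > 0):
            raise ValueError("flexion_angles must be strictly increasing")
        object.__setattr__(self, "flexion_angles", angles)

    def axis_direction(self, flexion_deg: float) -> np.ndarray:
        """Unit axis direction at one flexion angle (X-positive convention)."""
        c = np.deg2rad(self.coronal_drift(flexion_deg))
        h = np.deg2rad(self.horizontal_drift(flexion_deg))
        return unit(np.array([1.0, np.tan(c), np.tan(h)]))


@dataclass
class GroundTruth:
    """Exact per-frame axes and humeral geometry emitted by the generator."""

    flexion_deg: np.ndarray
    axis_points: np.ndarray  # (n, 3)
    axis_dirs: np.ndarray  # (n, 3), unit, positive X component
    medial_aspect: AspectCircle | None = None
    lateral_aspect: AspectCircle | None = None
    shaft_dir: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.flexion_deg = np.atleast_1d(np.asarray(self.flexion_deg, dtype=float))
        self.axis_points = np.atleast_2d(np.asarray(self.axis_points, dtype=float))
        self.axis_dirs = np.atleast_2d(np.asarray(self.axis_dirs, dtype=float))
        if not (len(self.flexion_deg) == len(self.axis_points) == len(self.axis_dirs)):
            raise ValueError("per-frame arrays must have equal length")
        norms = np.linalg.norm(self.axis_dirs, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("axis directions must be unit-norm")

    @property
    def n_frames(self) -> int:
        return len(self.flexion_deg)


@dataclass
class UlnaGeometry:
    """Reference proximal ulna: mesh, exact notch axis and landmarks."""

    mesh: trimesh.Trimesh
    notch_axis_point: np.ndarray
    notch_axis_dir: np.ndarray
    landmarks: np.ndarray  # (3, 3), on the notch surface in one cross-section
    params: ElbowParams


@dataclass(frozen=True)
class ImageVolume:
    """A scalar 3-D image with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("volume array must be rank 3")
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("spacing must be 3 positive components")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


def make_distal_humerus(params: ElbowParams) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Stylized distal humerus: a frustum along X whose planar end disks are
    the medial (at the origin) and lateral aspect circles.

    Returns the watertight mesh and a GroundTruth carrying the exact aspect
    circles and the shaft direction (+Y); the per-frame fields are empty
    until :func:`pose_sequence` fills them.
    """
    r_med, r_lat = params.medial_aspect_radius, params.lateral_aspect_radius
    length = params.transcondylar_length
    n_seg = int(np.ceil(2 * np.pi * max(r_med, r_lat) / params.mesh_resolution))
    if n_seg < 8:
        raise ValueError("mesh_resolution too coarse to represent the aspect disks")
    theta = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    ring = np.column_stack([np.cos(theta), np.sin(theta)])
    med_ring = np.column_stack([np.zeros(n_seg), r_med * ring])
    lat_ring = np.column_stack([np.full(n_seg, length), r_lat * ring])
    verts = np.vstack([med_ring, lat_ring, [[0.0, 0.0, 0.0]], [[length, 0.0, 0.0]]])
    c_med, c_lat = 2 * n_seg, 2 * n_seg + 1
    faces = []
    for i in range(n_seg):
        j = (i + 1) % n_seg
        # side quad, wound outward (normal away from the X axis)
        faces.append([i, n_seg + i, n_seg + j])
        faces.append([i, n_seg + j, j])
        # medial cap (outward normal -X) and lateral cap (+X)
        faces.append([c_med, j, i])
        faces.append([c_lat, n_seg + i, n_seg + j])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    if mesh.volume < 0:  # pragma: no cover - fix_normals orients outward
        mesh.invert()
    truth = GroundTruth(
        flexion_deg=np.zeros(0),
        axis_points=np.zeros((0, 3)),
        axis_dirs=np.zeros((0, 3)),
        medial_aspect=AspectCircle("medial", np.zeros(3), r_med, np.array([-1.0, 0, 0])),
        lateral_aspect=AspectCircle(
            "lateral", np.array([length, 0.0, 0.0]), r_lat, np.array([1.0, 0, 0])
        ),
        shaft_dir=np.array([0.0, 1.0, 0.0]),
    )
    return mesh, truth


def make_proximal_ulna(params: ElbowParams) -> UlnaGeometry:
    """Proximal ulna whose greater sigmoid notch is an exact cylinder arc.

    The bone is modeled as a C-shaped shell: an annular sector (inner
    radius = notch_radius) extruded along the mediolateral X axis.  The
    inner surface is the articular notch; its axis is the X axis through
    the origin.  The arc opens anteriorly with its deepest point (the
    "highest depression") at -Y, where the three registration landmarks are
    placed in the mid-width cross-section at +/-60 deg around mid-arc.
    """
    r = params.notch_radius
    R = r + params.notch_wall_thickness
    w = params.notch_width
    half_arc = np.deg2rad(params.notch_arc) / 2
    res = params.mesh_resolution
    n_arc = max(8, int(np.ceil(np.deg2rad(params.notch_arc) * R / res)))
    n_x = max(2, int(np.ceil(w / res)))  # layers along the extrusion (X)
    beta = np.linspace(-half_arc, half_arc, n_arc + 1)
    # closed outline of the annular-sector cross-section in the (y, z) plane:
    # inner arc (beta ascending) then outer arc back; mid-arc points at -Y
    inner = np.column_stack([-r * np.cos(beta), r * np.sin(beta)])
    outer = np.column_stack([-R * np.cos(beta[::-1]), R * np.sin(beta[::-1])])
    outline = np.vstack([inner, outer])
    m = len(outline)
    xs = np.linspace(-w / 2, w / 2, n_x + 1)
    verts = np.vstack(
        [np.column_stack([np.full(m, x), outline]) for x in xs]
    )

    def vid(i: int, j: int) -> int:
        return i * m + (j % m)

    quads = []
    for i in range(n_x):  # tube wall between consecutive layers
        for j in range(m):
            quads.append((vid(i, j), vid(i, j + 1), vid(i + 1, j + 1), vid(i + 1, j)))
    # end caps: pair inner-arc point j with its outer-arc partner m-1-j
    for j in range(n_arc):
        quads.append((vid(0, j + 1), vid(0, j), vid(0, m - 1 - j), vid(0, m - 2 - j)))
        quads.append((vid(n_x, j), vid(n_x, j + 1), vid(n_x, m - 2 - j), vid(n_x, m - 1 - j)))
    faces = []
    for (a, b, c, d) in quads:
        faces.append((a, b, c))
        faces.append((a, c, d))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    mesh.fix_normals()
    if mesh.volume < 0:  # pragma: no cover - fix_normals orients outward
        mesh.invert()
    lm_angles = np.deg2rad([-60.0, 0.0, 60.0])
    lm_angles = np.clip(lm_angles, -0.9 * half_arc, 0.9 * half_arc)
    landmarks = np.column_stack(
        [np.zeros(3), -r * np.cos(lm_angles), r * np.sin(lm_angles)]
    )
    return UlnaGeometry(
        mesh=mesh,
        notch_axis_point=np.zeros(3),
        notch_axis_dir=np.array([1.0, 0.0, 0.0]),
        landmarks=landmarks,
        params=params,
    )


def notch_vertex_mask(ulna: UlnaGeometry, tol: float | None = None) -> np.ndarray:
    """Vertices lying on the articular (inner cylinder) surface."""
    if tol is None:
        tol = ulna.params.mesh_resolution
    rel = ulna.mesh.vertices - ulna.notch_axis_point
    d = unit(ulna.notch_axis_dir)
    radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
    return np.abs(radial - ulna.params.notch_radius) < tol


def _frame_transform(traj: AxisTrajectory, flexion_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid transform posing the reference ulna at one flexion angle.

    The reference notch axis (X through the origin) is first aligned onto
    the frame's true axis line, then the body is rotated about that line by
    the flexion angle.  Returns (4x4 transform, axis_point, axis_dir).
    """
    d = traj.axis_direction(flexion_deg)
    q = np.asarray(traj.axis_point_offset(flexion_deg), dtype=float)
    R_align = align_vector_rotation(np.array([1.0, 0.0, 0.0]), d)
    A = make_transform(R_align, q)
    F = rigid_about_line(q, d, flexion_deg)
    return F @ A, q, d


def pose_sequence(
    ulna: UlnaGeometry,
    traj: AxisTrajectory,
    humerus_truth: GroundTruth,
) -> tuple[list[trimesh.Trimesh], list[np.ndarray], GroundTruth]:
    """Rigidly pose the reference ulna through the flexion sequence.

    Each frame's copy is rotated by its flexion angle about the frame's
    true axis (whose line the notch axis is first aligned onto), so the
    posed notch cylinder axis coincides with the stored ground-truth axis.
    Landmarks ride with the mesh.  Returns (meshes, landmarks per frame,
    ground truth with the humeral fields copied over).
    """
    meshes: list[trimesh.Trimesh] = []
    landmarks: list[np.ndarray] = []
    points, dirs = [], []
    for phi in traj.flexion_angles:
        T, q, d = _frame_transform(traj, float(phi))
        posed = ulna.mesh.copy()
        posed.apply_transform(T)
        meshes.append(posed)
        landmarks.append(apply_transform(T, ulna.landmarks))
        points.append(q)
        dirs.append(d)
    truth = GroundTruth(
        flexion_deg=traj.flexion_angles.copy(),
        axis_points=np.asarray(points),
        axis_dirs=np.asarray(dirs),
        medial_aspect=humerus_truth.medial_aspect,
        lateral_aspect=humerus_truth.lateral_aspect,
        shaft_dir=humerus_truth.shaft_dir,
    )
    return meshes, landmarks, truth


def add_vertex_noise(mesh: trimesh.Trimesh, sigma: float, seed: int) -> trimesh.Trimesh:
    """I.i.d. Gaussian displacement of every vertex; deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    noisy = mesh.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noisy.vertices = noisy.vertices + rng.normal(0.0, sigma, size=noisy.vertices.shape)
    return noisy


def jitter_landmarks(landmarks: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Gaussian jitter emulating manual landmark registration error."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    landmarks = np.asarray(landmarks, dtype=float)
    if sigma == 0:
        return landmarks.copy()
    rng = np.random.default_rng(seed)
    return landmarks + rng.normal(0.0, sigma, size=landmarks.shape)


def voxelize(mesh: trimesh.Trimesh, pitch: float) -> ImageVolume:
    """Binary occupancy volume of a watertight mesh ({0,1} intensities)."""
    grid = mesh.voxelized(pitch).fill()
    data = grid.matrix.astype(np.float32)
    origin = np.asarray(grid.transform[:3, 3], dtype=float)
    return ImageVolume(data=data, spacing=np.full(3, float(pitch)), origin=origin)


def sample_aspect_rim(aspect: AspectCircle, n_points: int = 24, seed: int | None = None,
                      sigma: float = 0.0) -> np.ndarray:
    """Points on an aspect circle's rim (optionally with Gaussian noise)."""
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    u = unit(np.cross(aspect.normal, np.eye(3)[int(np.argmin(np.abs(aspect.normal)))]))
    v = np.cross(aspect.normal, u)
    pts = aspect.center + aspect.radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return pts


# ---------------------------------------------------------------------------
# Trajectory presets
# ---------------------------------------------------------------------------

def _flexion_grid(n_frames: int, rom_deg: float) -> np.ndarray:
    if n_frames < 1:
        raise ValueError("need at least one frame")
    return np.linspace(0.0, rom_deg, n_frames)


def fixed_axis_trajectory(
    n_frames: int = DEFAULT_N_FRAMES, rom_deg: float = DEFAULT_ROM_DEG
) -> AxisTrajectory:
    """Hinge motion about the fixed transcondylar axis (zero drift)."""
    return AxisTrajectory(
        flexion_angles=_flexion_grid(n_frames, rom_deg),
        coronal_drift=lambda phi: 0.0,
        horizontal_drift=lambda phi: 0.0,
        axis_point_offset=lambda phi: np.zeros(3),
    )


def drifting_axis_trajectory(
    params: ElbowParams | None = None,
    n_frames: int = DEFAULT_N_FRAMES,
    rom_deg: float = DEFAULT_ROM_DEG,
    horizontal_max_deg: float = 47.0,
    coronal_max_deg: float = 12.3,
    window_crossing_deg: float = 31.0,
) -> AxisTrajectory:
    """Axis drift emulating the reported in-vivo migration pattern.

    The signed horizontal tilt sweeps quadratically from 0 to
    -horizontal_max_deg (unsigned magnitude 0 -> ~47 deg, increasing with
    flexion) and the coronal tilt to +coronal_max_deg.  The axis point
    migrates on the medial aspect plane so that the medial pierce point
    moves anterior-inferior -> posterior-superior and, combined with the
    horizontal tilt, the lateral pierce point moves posterior ->
    anterior; the quadratic shapes keep the lateral migration monotone and
    place the +/-20% isometric-window crossing at ``window_crossing_deg``
    (medial z is the binding coordinate), mirroring the reported
    "maximum extension to 30 deg" window.
    """
    p = params or ElbowParams()
    r_med = p.medial_aspect_radius
    s_star = window_crossing_deg / rom_deg
    # medial pierce-point percentages: y = -15 + 70 s^2, z = -10 + a s^2
    # with a chosen so |z| crosses 20% exactly at the window crossing
    z0_pct, y0_pct, y_gain = -10.0, -15.0, 70.0
    z_gain = (20.0 - z0_pct) / s_star**2

    def s(phi: float) -> float:
        return phi / rom_deg

    def offset(phi: float) -> np.ndarray:
        s2 = s(phi) ** 2
        return np.array(
            [
                0.0,
                r_med * (y0_pct + y_gain * s2) / 100.0,
                r_med * (z0_pct + z_gain * s2) / 100.0,
            ]
        )

    return AxisTrajectory(
        flexion_angles=_flexion_grid(n_frames, rom_deg),
        coronal_drift=lambda phi: coronal_max_deg * s(phi) ** 2,
        horizontal_drift=lambda phi: -horizontal_max_deg * s(phi) ** 2,
        axis_point_offset=offset,
    )


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixture(
    dir_path: str | Path,
    meshes: Sequence[trimesh.Trimesh],
    truth: GroundTruth,
    landmarks: Sequence[np.ndarray] | None = None,
    humerus_mesh: trimesh.Trimesh | None = None,
    rim_points_per_aspect: int = 24,
) -> dict[str, Path]:
    """Write a complete on-disk fixture for the pipeline.

    Layout: frame_%03d.ply per posed ulna, landmarks.csv
    (frame,landmark_id,x,y,z), truth.json, aspects.json (rim point samples,
    shaft direction and posterior hint) and optionally humerus.ply.
    Round-trips losslessly through :mod:`elbowaxis.io`.
    """
    from . import io as _io

    if len(meshes) == 0:
        raise ValueError("empty mesh list")
    if len(meshes) != truth.n_frames:
        raise ValueError("mesh count must match ground-truth frame count")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for i, mesh in enumerate(meshes):
        p = out / f"frame_{i:03d}.ply"
        _io.write_mesh(mesh, p)
        paths[f"frame_{i:03d}"] = p
    if landmarks is not None:
        paths["landmarks"] = _io.write_landmarks(out / "landmarks.csv", landmarks)
    paths["truth"] = _io.write_ground_truth(out / "truth.json", truth)
    if truth.medial_aspect is not None and truth.lateral_aspect is not None:
        aspects = {
            "medial_rim": sample_aspect_rim(truth.medial_aspect, rim_points_per_aspect).tolist(),
            "lateral_rim": sample_aspect_rim(truth.lateral_aspect, rim_points_per_aspect).tolist(),
            "shaft_dir": np.asarray(truth.shaft_dir, dtype=float).tolist(),
            "posterior_hint": [0.0, 0.0, 1.0],
        }
        p = out / "aspects.json"
        p.write_text(json.dumps(aspects, indent=1))
        paths["aspects"] = p
    if humerus_mesh is not None:
        p = out / "humerus.ply"
        _io.write_mesh(humerus_mesh, p)
        paths["humerus"] = p
    return paths
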