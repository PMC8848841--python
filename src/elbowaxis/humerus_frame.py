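"""Distal-humerus landmark coordinate system and flexion angles.

The frame is anchored on the two epicondylar faces ("aspects") of the
distal humerus, each modeled as a circle with a center, radius and plane
normal.  The X axis joins the medial and lateral aspect centers (the
transcondylar axis, pointing laterally), Z is perpendicular to X and the
humeral shaft and points posteriorly, and Y = Z x X points superiorly,
approximately along the shaft.  The origin is the medial aspect center
projected onto the humeral surface along -X (the medial epicondyle).

The elbow flexion angle is the dihedral angle between a coronal plane of
the proximal ulna and the humeral coronal plane; a sequence helper unfolds
the arccos ambiguity for flexion beyond 90 degrees using frame-to-frame
continuity, with 0 degrees at the maximum-extension pose of the sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import (
    GeometryError,
    Plane,
    circle_fit_2d,
    fit_plane_tls,
    signed_angle,
    unit,
)

__all__ = [
    "AspectCircle",
    "HumerusFrame",
    "FlexionAngle",
    "fit_aspect_circle",
    "build_frame",
    "flexion_angle",
    "flexion_sequence",
    "to_frame_coords",
    "from_frame_coords",
    "ulna_coronal_plane",
]


@dataclass(frozen=True)
class AspectCircle:
    """Circle fitted to one epicondylar face of the distal humerus."""

    side: str  # "medial" or "lateral"
    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("medial", "lateral"):
            raise ValueError(f"side must be 'medial' or 'lateral', got {self.side!r}")
        if self.radius <= 0:
            raise ValueError("aspect radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    @property
    def plane(self) -> Plane:
        return Plane(point=self.center, normal=self.normal)


@dataclass(frozen=True)
class HumerusFrame:
    origin: np.ndarray
    X: np.ndarray  # medial -> lateral (transcondylar)
    Y: np.ndarray  # superior, approximately along the shaft
    Z: np.ndarray  # posterior

    def __post_init__(self) -> None:
        for name in ("origin", "X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        """Rows are X, Y, Z: maps world vectors to frame coordinates."""
        return np.vstack([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class FlexionAngle:
    frame_index: int
    angle_deg: float


def fit_aspect_circle(rim_points: np.ndarray, side: str) -> AspectCircle:
    """Fit a plane (total least squares) then a circle to aspect rim points."""
    rim_points = np.asarray(rim_points, dtype=float)
    if rim_points.shape[0] < 8:
        raise GeometryError(f"need >= 8 rim points for the {side} aspect, got {rim_points.shape[0]}")
    plane, _ = fit_plane_tls(rim_points)
    xy = plane.to_2d(plane.project(rim_points))
    center2d, radius, rms = circle_fit_2d(xy)
    center = plane.to_3d(center2d)[0]
    return AspectCircle(side=side, center=center, radius=radius, normal=plane.normal, rms_residual=rms)


def build_frame(
    medial: AspectCircle,
    lateral: AspectCircle,
    shaft_dir: np.ndarray,
    posterior_hint: np.ndarray,
    humerus_mesh=None,
    *,
    side: str = "right",
) -> HumerusFrame:
    """Construct the landmark coordinate system from the two aspect circles.

    X joins the aspect centers toward the lateral side, Z = unit(X x shaft)
    is orthogonal to both and points posteriorly for consistent right-side
    input, and Y = Z x X completes the right-handed triad along the shaft.
    posterior_hint is a consistency check: a disagreement (usually a wrong
    side flag) raises a warning.  For a left elbow (``side='left'``) X is
    mirrored so that it still points laterally.
    """
    if medial.side != "medial" or lateral.side != "lateral":
        raise ValueError("pass the medial circle first and the lateral circle second")
    sep = lateral.center - medial.center
    if np.linalg.norm(sep) < 1e-9:
        raise GeometryError("aspect centers coincide")
    X = unit(sep)
    if side == "left":
        X = -X
    elif side != "right":
        raise ValueError("side must be 'right' or 'left'")
    shaft = unit(shaft_dir)
    if abs(float(X @ shaft)) > np.cos(np.deg2rad(5.0)):
        raise GeometryError("degenerate shaft: shaft direction within 5 deg of the transcondylar axis")
    Z = unit(np.cross(X, shaft))
    Y = np.cross(Z, X)  # == component of shaft orthogonal to X, so Y.shaft > 0
    if float(Z @ np.asarray(posterior_hint, dtype=float)) < 0:
        # Honoring the hint would either break right-handedness or flip Y
        # away from superior; keep the construction and flag the input.
        warnings.warn(
            "posterior hint is inconsistent with a right-handed frame whose Y "
            "points along the shaft; check the side flag and shaft direction"
        )
    origin = medial.center.copy()
    if humerus_mesh is not None:
        origin = _project_medial_origin(medial.center, X, humerus_mesh)
    return HumerusFrame(origin=origin, X=X, Y=Y, Z=Z)


def _project_medial_origin(center: np.ndarray, X: np.ndarray, mesh) -> np.ndarray:
    """Ray-cast the medial aspect center along -X onto the humeral surface."""
    from ._geometry import ray_mesh_hits

    # start slightly inside the bone so a center already on the surface
    # projects onto itself
    start = center + 1e-3 * X
    hits = ray_mesh_hits(start, -X, np.asarray(mesh.triangles))
    if len(hits) == 0:
        warnings.warn("medial origin ray missed the humerus mesh; using the aspect center")
        return center.copy()
    return start + float(hits[0]) * (-X)


def flexion_angle(ulna_plane: Plane, humerus_plane: Plane, frame_index: int = 0) -> FlexionAngle:
    """Dihedral angle between the ulnar and humeral coronal planes.

    Uses arccos(|n1 . n2|), which folds at 90 degrees; use
    :func:`flexion_sequence` for full-range sequences.
    """
    c = abs(float(ulna_plane.normal @ humerus_plane.normal))
    angle = float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))
    return FlexionAngle(frame_index=frame_index, angle_deg=angle)


def flexion_sequence(
    ulna_planes: list[Plane],
    humerus_plane: Plane,
    hinge_dir: np.ndarray,
) -> np.ndarray:
    """Unfolded flexion angles (deg) for a motion sequence.

    The signed dihedral angle about the hinge direction (the frame X axis)
    is tracked with frame-to-frame normal continuity, then referenced to
    the first frame (the maximum-extension pose), so the result covers
    [0, 180) without the arccos fold.
    """
    if not ulna_planes:
        raise ValueError("empty sequence")
    hinge = unit(hinge_dir)
    n_h = humerus_plane.normal
    angles = []
    prev = None
    for plane in ulna_planes:
        n_u = plane.normal
        if prev is not None and float(n_u @ prev) < 0:
            n_u = -n_u
        prev = n_u
        angles.append(signed_angle(n_h, n_u, hinge))
    theta = np.unwrap(np.deg2rad(np.asarray(angles)))
    theta = np.rad2deg(theta)
    return np.abs(theta - theta[0])


def to_frame_coords(point: np.ndarray, frame: HumerusFrame) -> np.ndarray:
    """Coordinates of a world point on the frame's X, Y, Z axes."""
    point = np.asarray(point, dtype=float)
    return frame.rotation @ (point - frame.origin)


def from_frame_coords(coords: np.ndarray, frame: HumerusFrame) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return frame.origin + frame.rotation.T @ coords


def ulna_coronal_plane(mesh, axis_point: np.ndarray, axis_dir: np.ndarray) -> Plane:
    """Coronal plane of the proximal ulna for flexion measurement.

    The plane contains the rotation axis and the direction from the axis to
    the bone centroid (the olecranon side), so it rotates rigidly with the
    ulna and its dihedral angle against the humeral coronal plane tracks
    flexion.
    """
    d = unit(axis_dir)
    e = np.asarray(mesh.centroid, dtype=float) - np.asarray(axis_point, dtype=float)
    e_perp = e - (e @ d) * d
    normal = unit(np.cross(d, e_perp))
    return Plane(point=np.asarray(axis_point, dtype=float), normal=normal)
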