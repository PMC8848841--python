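"""Instantaneous rotation axis of the ulnohumeral joint from one posed ulna.

The construction follows the articular geometry of the greater sigmoid
notch, which wraps the humeral trochlea as a near-cylindrical arc:

1. a plane is fitted through the three registered landmarks in the deepest
   part of the notch (a notch cross-section, so its normal is the
   mediolateral direction);
2. eleven parallel planes at 1 mm offsets are swept along that normal;
3. each plane's intersection with the bone surface is chained into
   polylines, and the smooth sub-arc nearest the landmarks (the articular
   arc, not the far cortex) is kept;
4. a least-squares circle is fitted to every section arc;
5. the total-least-squares line through the eleven circle centers is the
   instantaneous rotation axis.

A finite-helical-axis (screw displacement) estimator from rigid point-set
registration between consecutive frames is provided as an independent
validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from ._geometry import (
    GeometryError,
    Plane,
    arc_extent_deg,
    circle_fit_2d,
    fit_line_tls,
    helical_from_transform,
    kabsch,
    line_point_distance,
    unit,
)

__all__ = [
    "PlanarCurve",
    "CircleFit",
    "RotationAxis",
    "HelicalAxisResult",
    "EstimatorConfig",
    "AxisEstimationError",
    "plane_from_landmarks",
    "section_curve",
    "offset_planes",
    "fit_circle",
    "fit_axis",
    "estimate_instantaneous_axis",
    "helical_axis_oracle",
]


class AxisEstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlanarCurve:
    """An ordered polyline lying in one plane."""

    points: np.ndarray
    plane: Plane
    closed: bool = False

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        # planarity guard: intersection/resampling keeps points on the plane
        d = np.abs(self.plane.signed_distance(pts))
        if d.max() > 1e-6 * max(1.0, np.abs(pts).max()):
            raise GeometryError("curve points do not lie on the stated plane")


@dataclass(frozen=True)
class CircleFit:
    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms_residual: float
    n_points: int = 0
    arc_extent_deg: float = 360.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class RotationAxis:
    point: np.ndarray
    direction: np.ndarray
    rms_residual: float
    frame_index: int = 0
    circle_fits: tuple[CircleFit, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))

    def distance_to_point(self, point: np.ndarray) -> float:
        return line_point_distance(point, self.point, self.direction)


@dataclass(frozen=True)
class HelicalAxisResult:
    axis: RotationAxis
    angle_deg: float
    translation_mm: float
    reliable: bool


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable knobs of the notch-section axis estimator.

    Offset spacing/count default to the 1 mm / 11 curve construction;
    resampling and corner detection control how the articular arc is
    isolated from the closed section loop of the bone surface.
    """

    offset_spacing: float = 1.0
    offset_count: int = 11
    resample_spacing: float = 0.75
    corner_angle_deg: float = 50.0
    corner_baseline: float = 4.0
    corner_trim_factor: float = 0.25
    min_curve_points: int = 8
    min_arc_extent_deg: float = 60.0
    min_center_span: float = 1.0
    lateral_hint: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    surface_tol: float | None = None
    circle_refine_steps: int = 1


def plane_from_landmarks(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> Plane:
    """Plane through the three registered notch landmarks."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(n)
    if area <= 1e-6:
        raise GeometryError("landmarks are (near-)collinear; plane undefined")
    return Plane(point=(p1 + p2 + p3) / 3.0, normal=n)


def offset_planes(
    base: Plane, direction: np.ndarray, spacing: float = 1.0, count: int = 11
) -> list[Plane]:
    """`count` planes parallel to `base` at symmetric signed offsets.

    Offsets are centered on the base plane, e.g. -5..+5 mm for the default
    1 mm spacing and 11 planes, measured along `direction`.
    """
    if count < 2:
        raise ValueError("need at least 2 planes to define an axis")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    d = unit(direction)
    offsets = (np.arange(count) - (count - 1) / 2.0) * spacing
    return [Plane(point=base.point + o * d, normal=base.normal) for o in offsets]


# ---------------------------------------------------------------------------
# Section-curve extraction
# ---------------------------------------------------------------------------

def _chain_segments(segments: np.ndarray, tol: float = 1e-7) -> list[tuple[np.ndarray, bool]]:
    """Chain unordered intersection segments into ordered polylines.

    Endpoints are matched with a KD-tree at tolerance `tol`; returns a list
    of (points, closed) in deterministic order.
    """
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    segments = segments[lengths > tol]  # drop degenerate slivers
    n = len(segments)
    if n == 0:
        return []
    ends = segments.reshape(-1, 3)  # endpoint 2*i, 2*i+1 belong to segment i
    tree = cKDTree(ends)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    # union endpoints into shared nodes
    parent = np.arange(len(ends))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    node_of = np.array([find(i) for i in range(len(ends))])
    # adjacency: node -> list of (segment, other_node)
    adj: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        a, b = node_of[2 * i], node_of[2 * i + 1]
        adj.setdefault(a, []).append((i, b))
        adj.setdefault(b, []).append((i, a))
    used = np.zeros(n, dtype=bool)
    polylines: list[tuple[np.ndarray, bool]] = []
    # open chains first: start from degree-1 nodes, then remaining loops
    starts = sorted([k for k, v in adj.items() if len(v) == 1]) + sorted(adj.keys())
    for start in starts:
        for seg, _ in adj[start]:
            if used[seg]:
                continue
            chain_nodes = [start]
            node = start
            while True:
                nxt = None
                for s, other in adj[node]:
                    if not used[s]:
                        nxt = (s, other)
                        break
                if nxt is None:
                    break
                used[nxt[0]] = True
                node = nxt[1]
                chain_nodes.append(node)
            pts = ends[chain_nodes]
            closed = len(chain_nodes) > 2 and chain_nodes[0] == chain_nodes[-1]
            if closed:
                pts = pts[:-1]
            if len(pts) >= 2:
                polylines.append((pts, closed))
    return polylines


def _resample_polyline(points: np.ndarray, closed: bool, spacing: float) -> np.ndarray:
    """Uniform arc-length resampling (linear interpolation, stays in-plane)."""
    pts = points
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total < spacing:
        return points.copy()
    m = max(int(round(total / spacing)), 2)
    t = np.linspace(0.0, total, m, endpoint=not closed)
    out = np.column_stack([np.interp(t, arclen, pts[:, k]) for k in range(3)])
    return out


def _split_at_corners(
    points: np.ndarray,
    closed: bool,
    spacing: float,
    baseline: float,
    angle_deg: float,
    trim_factor: float = 0.25,
) -> list[np.ndarray]:
    """Split a polyline into smooth pieces at sharp turning points.

    The turning angle at each sample is measured over a +/- `baseline`
    chord (robust to vertex noise, insensitive to gentle arc curvature);
    the over-threshold region already brackets a sharp corner, so only a
    small extra margin (`trim_factor` baselines) is discarded around it to
    keep as much of the articular arc as possible for the circle fits.
    """
    m = len(points)
    k = max(1, int(round(baseline / spacing)))
    if m <= 2 * k + 1:
        return [points]
    # light smoothing for corner *detection* only
    if closed:
        padded = np.vstack([points[-1:], points, points[:1]])
        smooth = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    else:
        smooth = points.copy()
        smooth[1:-1] = (points[:-2] + points[1:-1] + points[2:]) / 3.0
    idx = np.arange(m)
    if closed:
        prev_i, next_i = (idx - k) % m, (idx + k) % m
        valid = np.ones(m, dtype=bool)
    else:
        prev_i, next_i = np.clip(idx - k, 0, m - 1), np.clip(idx + k, 0, m - 1)
        valid = (idx >= k) & (idx <= m - 1 - k)
    v1 = smooth[idx] - smooth[prev_i]
    v2 = smooth[next_i] - smooth[idx]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = valid & (n1 > 1e-12) & (n2 > 1e-12)
    cosang = np.ones(m)
    cosang[ok] = np.sum(v1[ok] * v2[ok], axis=1) / (n1[ok] * n2[ok])
    turning = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    corners = np.where(turning > angle_deg)[0]
    if len(corners) == 0:
        return [points]
    kw = max(1, int(round(k * trim_factor)))
    cut = np.zeros(m, dtype=bool)
    for c in corners:
        lo, hi = c - kw, c + kw
        if closed:
            cut[np.arange(lo, hi + 1) % m] = True
        else:
            cut[max(0, lo) : min(m, hi + 1)] = True
    pieces: list[np.ndarray] = []
    if closed:
        # rotate so the sequence starts inside a cut region
        first_cut = int(np.where(cut)[0][0])
        order = np.roll(np.arange(m), -first_cut)
        points, cut = points[order], cut[order]
    run_start = None
    for i in range(m):
        if not cut[i] and run_start is None:
            run_start = i
        elif cut[i] and run_start is not None:
            pieces.append(points[run_start:i])
            run_start = None
    if run_start is not None:
        pieces.append(points[run_start:])
    return [p for p in pieces if len(p) >= 2]


def section_curve(
    mesh: trimesh.Trimesh,
    plane: Plane,
    near: np.ndarray,
    *,
    config: EstimatorConfig | None = None,
) -> PlanarCurve:
    """Intersection of the bone surface with a plane, reduced to the
    articular arc nearest `near` (the landmark centroid).

    A plane through a closed bone surface yields closed loops that contain
    both the notch arc and the far cortex; the loop(s) are resampled
    uniformly, split at sharp corners, and the smooth piece whose minimum
    distance to `near` is smallest is returned.
    """
    cfg = config or EstimatorConfig()
    near = np.asarray(near, dtype=float)
    segments = trimesh.intersections.mesh_plane(mesh, plane.normal, plane.point)
    if len(segments) == 0:
        raise AxisEstimationError("plane does not intersect the mesh")
    candidates: list[tuple[float, np.ndarray, bool]] = []
    for pts, closed in _chain_segments(np.asarray(segments, dtype=float)):
        res = _resample_polyline(pts, closed, cfg.resample_spacing)
        pieces = _split_at_corners(
            res, closed, cfg.resample_spacing, cfg.corner_baseline,
            cfg.corner_angle_deg, cfg.corner_trim_factor,
        )
        piece_closed = closed and len(pieces) == 1
        for piece in pieces:
            dist = float(np.min(np.linalg.norm(piece - near, axis=1)))
            candidates.append((dist, piece, piece_closed))
    if not candidates:  # pragma: no cover
        raise AxisEstimationError("no usable intersection polyline")
    candidates.sort(key=lambda c: c[0])
    dist, pts, closed = candidates[0]
    if len(pts) < cfg.min_curve_points:
        raise AxisEstimationError(
            f"selected section polyline has only {len(pts)} points "
            f"(< {cfg.min_curve_points})"
        )
    # snap onto the plane to remove accumulated float error
    pts = plane.project(pts)
    return PlanarCurve(points=pts, plane=plane, closed=closed)


def fit_circle(curve: PlanarCurve, *, config: EstimatorConfig | None = None) -> CircleFit:
    """Least-squares circle of a planar section arc.

    Kasa algebraic seed plus one geometric Gauss-Newton refinement; arcs
    subtending less than `min_arc_extent_deg` as seen from the algebraic
    center are rejected as ill-conditioned.
    """
    cfg = config or EstimatorConfig()
    if len(curve.points) < cfg.min_curve_points:
        raise AxisEstimationError(
            f"need >= {cfg.min_curve_points} points for a circle fit, got {len(curve.points)}"
        )
    xy = curve.plane.to_2d(curve.points)
    center2d, radius, rms = circle_fit_2d(xy, refine_steps=cfg.circle_refine_steps)
    extent = arc_extent_deg(xy, center2d)
    if extent < cfg.min_arc_extent_deg:
        raise AxisEstimationError(
            f"ill-conditioned arc: extent {extent:.1f} deg < {cfg.min_arc_extent_deg} deg"
        )
    center = curve.plane.to_3d(center2d)[0]
    return CircleFit(
        center=center,
        radius=radius,
        normal=curve.plane.normal,
        rms_residual=rms,
        n_points=len(curve.points),
        arc_extent_deg=extent,
    )


def fit_axis(
    centers: np.ndarray,
    *,
    frame_index: int = 0,
    lateral_hint: np.ndarray | None = None,
    config: EstimatorConfig | None = None,
    circle_fits: tuple[CircleFit, ...] = (),
) -> RotationAxis:
    """Total-least-squares line through the per-section circle centers."""
    cfg = config or EstimatorConfig()
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 3:
        raise AxisEstimationError("need >= 3 circle centers to fit an axis")
    point, direction, rms, span = fit_line_tls(centers)
    if span < cfg.min_center_span:
        raise AxisEstimationError(
            f"degenerate center spread: span {span:.3f} mm < {cfg.min_center_span} mm"
        )
    hint = cfg.lateral_hint if lateral_hint is None else np.asarray(lateral_hint, dtype=float)
    d = float(direction @ hint)
    if abs(d) < 1e-9:
        # hint orthogonal to the axis: fall back to largest component positive
        if direction[int(np.argmax(np.abs(direction)))] < 0:
            direction = -direction
    elif d < 0:
        direction = -direction
    return RotationAxis(
        point=point,
        direction=direction,
        rms_residual=rms,
        frame_index=frame_index,
        circle_fits=circle_fits,
    )


def estimate_instantaneous_axis(
    mesh: trimesh.Trimesh,
    landmarks: np.ndarray,
    config: EstimatorConfig | None = None,
    *,
    frame_index: int = 0,
) -> RotationAxis:
    """Full notch-section axis construction for one posed ulna."""
    cfg = config or EstimatorConfig()
    landmarks = np.asarray(landmarks, dtype=float)
    if landmarks.shape != (3, 3):
        raise ValueError("expected exactly 3 landmark points")
    if cfg.surface_tol is not None:
        tree = cKDTree(mesh.vertices)
        d, _ = tree.query(landmarks)
        if np.any(d > cfg.surface_tol):
            raise AxisEstimationError(
                f"landmark farther than {cfg.surface_tol} mm from the mesh surface"
            )
    base = plane_from_landmarks(*landmarks)
    centroid = landmarks.mean(axis=0)
    planes = offset_planes(base, base.normal, cfg.offset_spacing, cfg.offset_count)
    centers = []
    fits: list[CircleFit] = []
    for i, plane in enumerate(planes):
        near_i = centroid + float((plane.point - base.point) @ base.normal) * base.normal
        try:
            curve = section_curve(mesh, plane, near_i, config=cfg)
            fit = fit_circle(curve, config=cfg)
        except (AxisEstimationError, GeometryError) as exc:
            raise AxisEstimationError(f"offset index {i}: {exc}") from exc
        centers.append(fit.center)
        fits.append(fit)
    return fit_axis(
        np.asarray(centers),
        frame_index=frame_index,
        config=cfg,
        circle_fits=tuple(fits),
    )


def helical_axis_oracle(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    *,
    min_angle_deg: float = 1.0,
) -> HelicalAxisResult:
    """Finite helical (screw displacement) axis between two corresponding
    rigid poses of the same bone; independent of the notch construction.
    """
    va, vb = np.asarray(mesh_a.vertices), np.asarray(mesh_b.vertices)
    if va.shape != vb.shape:
        raise ValueError("meshes must be vertex-corresponding poses of one body")
    R, t = kabsch(va, vb)
    angle, direction, point, tau = helical_from_transform(R, t)
    reliable = angle >= min_angle_deg
    axis = RotationAxis(
        point=point,
        direction=direction if reliable else np.array([1.0, 0.0, 0.0]),
        rms_residual=0.0,
    )
    return HelicalAxisResult(axis=axis, angle_deg=angle, translation_mm=tau, reliable=reliable)
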