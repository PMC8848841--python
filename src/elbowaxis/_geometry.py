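"""Low-level geometric primitives shared across the pipeline.

Planes, rigid transforms, least-squares circle and line fits, and the
finite-helical-axis decomposition. Everything works in millimetres and
degrees at the API surface; radians are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_EPS = 1e-12


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


def unit(v: np.ndarray, *, tol: float = _EPS) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < tol:
        raise GeometryError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.point) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(points)
        return points - d[:, None] * self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic)."""
        n = self.normal
        seed = np.eye(3)[int(np.argmin(np.abs(n)))]
        u = unit(np.cross(n, seed))
        v = np.cross(n, u)
        return u, v

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(points) - self.point
        return np.column_stack([rel @ u, rel @ v])

    def to_3d(self, coords_2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        coords_2d = np.atleast_2d(coords_2d)
        return self.point + coords_2d[:, :1] * u + coords_2d[:, 1:2] * v


def rotation_about_axis(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about a unit direction through the origin."""
    d = unit(direction)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * d).as_matrix()


def rigid_about_line(point: np.ndarray, direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """4x4 rotation about the line (point, direction)."""
    point = np.asarray(point, dtype=float)
    R = rotation_about_axis(direction, angle_deg)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = point - R @ point
    return T


def make_transform(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    return T


def apply_transform(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return points @ T[:3, :3].T + T[:3, 3]


def align_vector_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a, b = unit(a), unit(b)
    c = np.cross(a, b)
    s = np.linalg.norm(c)
    d = float(a @ b)
    if s < 1e-14:
        if d > 0:
            return np.eye(3)
        # 180 degrees: rotate about any perpendicular axis
        perp = unit(np.cross(a, np.eye(3)[int(np.argmin(np.abs(a)))]))
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    axis = c / s
    angle = np.arctan2(s, d)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def signed_angle(a: np.ndarray, b: np.ndarray, about: np.ndarray) -> float:
    """Signed angle (deg) from a to b about the `about` direction."""
    about = unit(about)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.rad2deg(np.arctan2(np.cross(a, b) @ about, a @ b)))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with Q ~ P @ R.T + t.

    Closed-form point-set registration on corresponding points via SVD of
    the cross-covariance, with the determinant sign fix for reflections.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise GeometryError("need >= 3 corresponding points of equal shape")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def helical_from_transform(R: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Finite helical (screw) decomposition of a rigid transform.

    Returns (angle_deg, axis_direction, axis_point, translation_along_axis).
    The axis point is the point on the screw axis closest to the origin.
    For angles near zero the direction is numerically meaningless; callers
    must check the angle before trusting it.
    """
    rot = Rotation.from_matrix(R)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-14:
        return 0.0, np.array([1.0, 0.0, 0.0]), np.zeros(3), float(np.linalg.norm(t))
    d = rotvec / angle
    tau = float(t @ d)
    t_perp = t - tau * d
    # Solve (I - R) p = t_perp for the axis point in the plane normal to d.
    A = np.eye(3) - R
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ d) * d
    return float(np.rad2deg(angle)), d, p, tau


def fit_plane_tls(points: np.ndarray) -> tuple[Plane, float]:
    """Total-least-squares plane through >= 3 points; returns (plane, rms)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise GeometryError("need >= 3 points to fit a plane")
    c = points.mean(axis=0)
    X = points - c
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[1] < 1e-9:
        raise GeometryError("points are (near-)collinear; plane undefined")
    normal = Vt[2]
    rms = float(np.sqrt(np.mean((X @ normal) ** 2)))
    return Plane(point=c, normal=normal), rms


def fit_line_tls(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Total-least-squares line (principal axis of the centered covariance).

    Returns (centroid, unit direction, rms perpendicular distance, span),
    where span is the extent of the points projected onto the direction.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise GeometryError("need >= 2 points to fit a line")
    c = points.mean(axis=0)
    X = points - c
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    d = Vt[0]
    proj = X @ d
    span = float(proj.max() - proj.min())
    perp = X - np.outer(proj, d)
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return c, d, rms, span


def circle_fit_2d(xy: np.ndarray, *, refine_steps: int = 1) -> tuple[np.ndarray, float, float]:
    """Least-squares circle in the plane: Kasa algebraic seed plus a fixed
    number of Gauss-Newton refinements of the geometric (radial) residual.

    Returns (center_2d, radius, rms_radial_residual).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.shape[0] < 3:
        raise GeometryError("need >= 3 points to fit a circle")
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - lstsq rarely fails
        raise GeometryError("algebraic circle fit failed") from exc
    cx, cy, c0 = sol
    r2 = c0 + cx**2 + cy**2
    if r2 <= 0:
        raise GeometryError("degenerate circle fit (non-positive radius)")
    center = np.array([cx, cy])
    radius = float(np.sqrt(r2))
    for _ in range(max(0, refine_steps)):
        diff = xy - center
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist < 1e-12):
            break
        res = dist - radius
        J = np.column_stack([-diff[:, 0] / dist, -diff[:, 1] / dist, -np.ones_like(dist)])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        center = center + step[:2]
        radius = float(radius + step[2])
    diff = xy - center
    dist = np.linalg.norm(diff, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    if radius <= 0:
        raise GeometryError("degenerate circle fit (non-positive radius)")
    return center, radius, rms


def arc_extent_deg(xy: np.ndarray, center: np.ndarray) -> float:
    """Angular extent (deg) subtended by the points as seen from center."""
    rel = np.asarray(xy, dtype=float) - np.asarray(center, dtype=float)
    ang = np.sort(np.arctan2(rel[:, 1], rel[:, 0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.rad2deg(2 * np.pi - gaps.max()))


def ray_mesh_hits(
    origin: np.ndarray, direction: np.ndarray, triangles: np.ndarray, *, eps: float = 1e-9
) -> np.ndarray:
    """Ray distances to every intersected triangle (Moller-Trumbore).

    `triangles` is (n, 3, 3); returns the sorted positive hit distances.
    Brute-force over all triangles, which is fine at bone-mesh sizes.
    """
    origin = np.asarray(origin, dtype=float)
    d = unit(direction)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(d[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ d)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
    return np.sort(t[hit])


def line_point_distance(point: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray) -> float:
    d = unit(line_dir)
    rel = np.asarray(point, dtype=float) - np.asarray(line_point, dtype=float)
    return float(np.linalg.norm(rel - (rel @ d) * d))
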