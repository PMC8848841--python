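"""Where the rotation axis pierces the epicondylar faces of the humerus.

Each frame's instantaneous axis is intersected with the planes of the
medial and lateral aspect circles; the pierce points are expressed in the
humeral landmark frame, normalized by the aspect radius (so +/-100% spans
the aspect disk), classified into anterior/posterior x inferior/superior
quadrants, and screened with the +/-20% isometric window: frames whose
axis pierces within 20% of both aspect centers simultaneously approximate
the poses in which a collateral-ligament graft anchored near the centers
stays isometric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import GeometryError
from .axis_estimation import RotationAxis
from .humerus_frame import AspectCircle, HumerusFrame, to_frame_coords

__all__ = [
    "AspectIntersection",
    "AxisAngles",
    "WindowReport",
    "intersect_axis_with_aspect",
    "normalize_intersection",
    "classify_quadrant",
    "axis_angles",
    "isometric_window",
]

QUADRANTS = (
    "anterior-superior",
    "posterior-superior",
    "anterior-inferior",
    "posterior-inferior",
)


@dataclass(frozen=True)
class AspectIntersection:
    frame_index: int
    side: str
    point: np.ndarray  # world mm
    y_pct: float
    z_pct: float
    quadrant: str
    tie: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if not (np.isfinite(self.y_pct) and np.isfinite(self.z_pct)):
            raise ValueError("normalized coordinates must be finite")


@dataclass(frozen=True)
class AxisAngles:
    """Angles between the axis and the transcondylar X axis after
    projection into the coronal (XY) and horizontal (XZ) planes.

    Unsigned values in [0, 90] match the way the summary statistics are
    reported; the signed values retain trend directionality.
    """

    frame_index: int
    coronal_deg: float
    horizontal_deg: float
    coronal_signed_deg: float
    horizontal_signed_deg: float


@dataclass(frozen=True)
class WindowReport:
    threshold_pct: float
    selected_frames: tuple[int, ...]
    flexion_range: tuple[float, float] | None


def intersect_axis_with_aspect(axis: RotationAxis, aspect: AspectCircle) -> np.ndarray:
    """Line-plane intersection of the axis with the aspect circle's plane."""
    d = axis.direction
    n = aspect.normal
    denom = float(d @ n)
    if abs(denom) <= 1e-6:
        raise GeometryError("axis parallel to aspect plane")
    t = float((aspect.center - axis.point) @ n) / denom
    return axis.point + t * d


def normalize_intersection(
    point: np.ndarray,
    frame: HumerusFrame,
    aspect: AspectCircle,
    *,
    lateral_reference: str = "lateral_center",
) -> tuple[float, float]:
    """Radius-normalized (y%, z%) of a pierce point on one aspect.

    Medial points are referenced to the frame origin (the projected medial
    aspect center); lateral points to the lateral aspect center expressed
    on the same frame axes (``lateral_reference='medial_origin'`` switches
    to the single medial origin instead).
    """
    if aspect.radius <= 0:
        raise ValueError("aspect radius must be positive")
    point = np.asarray(point, dtype=float)
    if aspect.side == "lateral" and lateral_reference == "lateral_center":
        rel = frame.rotation @ (point - aspect.center)
    elif aspect.side == "lateral" and lateral_reference != "medial_origin":
        raise ValueError("lateral_reference must be 'lateral_center' or 'medial_origin'")
    else:
        rel = to_frame_coords(point, frame)
    y_pct = float(rel[1] / aspect.radius * 100.0)
    z_pct = float(rel[2] / aspect.radius * 100.0)
    return y_pct, z_pct


def classify_quadrant(y_pct: float, z_pct: float) -> tuple[str, bool]:
    """Quadrant of a normalized pierce point; exact zeros go to the
    positive (posterior/superior) class with a tie flag."""
    tie = y_pct == 0.0 or z_pct == 0.0
    ap = "posterior" if z_pct >= 0 else "anterior"
    si = "superior" if y_pct >= 0 else "inferior"
    return f"{ap}-{si}", tie


def make_intersection(
    axis: RotationAxis,
    frame: HumerusFrame,
    aspect: AspectCircle,
    *,
    lateral_reference: str = "lateral_center",
) -> AspectIntersection:
    """Convenience: intersect, normalize and classify in one call."""
    point = intersect_axis_with_aspect(axis, aspect)
    y_pct, z_pct = normalize_intersection(
        point, frame, aspect, lateral_reference=lateral_reference
    )
    quadrant, tie = classify_quadrant(y_pct, z_pct)
    return AspectIntersection(
        frame_index=axis.frame_index,
        side=aspect.side,
        point=point,
        y_pct=y_pct,
        z_pct=z_pct,
        quadrant=quadrant,
        tie=tie,
    )


def axis_angles(axis: RotationAxis, frame: HumerusFrame) -> AxisAngles:
    """Coronal- and horizontal-plane angles between the axis and X."""
    d = axis.direction
    dx, dy, dz = float(d @ frame.X), float(d @ frame.Y), float(d @ frame.Z)
    cor_norm = np.hypot(dx, dy)
    hor_norm = np.hypot(dx, dz)
    if cor_norm < 1e-9 or hor_norm < 1e-9:
        raise GeometryError("axis parallel to a projection plane normal; angle undefined")
    coronal = float(np.rad2deg(np.arctan2(dy, dx)))
    horizontal = float(np.rad2deg(np.arctan2(dz, dx)))
    return AxisAngles(
        frame_index=axis.frame_index,
        coronal_deg=abs(coronal),
        horizontal_deg=abs(horizontal),
        coronal_signed_deg=coronal,
        horizontal_signed_deg=horizontal,
    )


def isometric_window(
    intersections: pd.DataFrame,
    threshold_pct: float = 20.0,
    flexion_by_frame: dict[int, float] | None = None,
) -> WindowReport:
    """Frames whose pierce points fall within +/-threshold% of both aspect
    centers on both sides simultaneously.

    `intersections` is a tidy table with columns frame, side, y_pct, z_pct
    (one medial and one lateral row per frame).
    """
    required = {"frame", "side", "y_pct", "z_pct"}
    if not required.issubset(intersections.columns):
        raise ValueError(f"intersections table needs columns {sorted(required)}")
    selected = []
    for frame_idx, grp in intersections.groupby("frame"):
        sides = set(grp["side"])
        if not {"medial", "lateral"}.issubset(sides):
            raise ValueError(f"frame {frame_idx} is missing a side")
        ok = bool(
            (grp["y_pct"].abs() <= threshold_pct).all()
            and (grp["z_pct"].abs() <= threshold_pct).all()
        )
        if ok:
            selected.append(int(frame_idx))
    selected.sort()
    flexion_range = None
    if flexion_by_frame is not None and selected:
        vals = [flexion_by_frame[f] for f in selected]
        flexion_range = (float(min(vals)), float(max(vals)))
    return WindowReport(
        threshold_pct=float(threshold_pct),
        selected_frames=tuple(selected),
        flexion_range=flexion_range,
    )
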