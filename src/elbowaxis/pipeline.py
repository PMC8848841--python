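"""Configuration-driven end-to-end run: meshes in, kinematics tables out.

Stages: load the per-frame ulna meshes and landmarks, fit the humeral
aspect circles and landmark frame, estimate each frame's instantaneous
rotation axis from the notch sections, measure flexion angles, map the
axis pierce points onto both aspects, screen with the isometric window,
and run the trend tests and angle summaries.  The run is a pure function
of (files, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from ._geometry import Plane
from .axis_estimation import (
    AxisEstimationError,
    EstimatorConfig,
    RotationAxis,
    estimate_instantaneous_axis,
)
from .humerus_frame import (
    HumerusFrame,
    build_frame,
    fit_aspect_circle,
    flexion_sequence,
    ulna_coronal_plane,
)
from .intersection_mapping import (
    WindowReport,
    axis_angles,
    isometric_window,
    make_intersection,
)
from .stats import TrendResult, circular_or_linear_summary, linear_trend

logger = logging.getLogger("elbowaxis")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_fixture", "PRESETS"]

PRESETS = ("fixed_axis", "drifting_axis", "noisy")


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: str | Path = "."
    frame_pattern: str = "frame_*.ply"
    landmarks_path: str | Path | None = None  # default: <input_dir>/landmarks.csv
    aspects_path: str | Path | None = None  # default: <input_dir>/aspects.json
    humerus_path: str | Path | None = None  # default: <input_dir>/humerus.ply if present
    offset_spacing: float = 1.0
    offset_count: int = 11
    isometric_threshold_pct: float = 20.0
    side: str = "right"
    lateral_reference: str = "lateral_center"
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | Path | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.offset_count < 3 or self.offset_count % 2 == 0:
            raise ValueError("offset_count must be an odd number >= 3")
        if self.isometric_threshold_pct <= 0:
            raise ValueError("isometric threshold must be positive")
        if self.offset_spacing <= 0:
            raise ValueError("offset spacing must be positive")


@dataclass
class PipelineResult:
    frame: HumerusFrame
    axes: dict[int, RotationAxis]
    flexion_deg: dict[int, float]
    intersections: pd.DataFrame
    angles: pd.DataFrame
    window: WindowReport
    trends: dict[str, TrendResult]
    summaries: dict[str, tuple[float, float, float, float]]
    failed_frames: dict[int, str] = field(default_factory=dict)
    n_frames_total: int = 0

    @property
    def exit_code(self) -> int:
        """0 ok, 1 partial (> 20% of frames failed)."""
        if self.n_frames_total and len(self.failed_frames) > 0.2 * self.n_frames_total:
            return 1
        return 0


def _resolve(config: PipelineConfig, attr: str, default_name: str) -> Path | None:
    explicit = getattr(config, attr)
    if explicit is not None:
        return Path(explicit)
    candidate = Path(config.input_dir) / default_name
    return candidate if candidate.exists() else None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    input_dir = Path(config.input_dir)
    mesh_paths = sorted(input_dir.glob(config.frame_pattern))
    if not mesh_paths:
        raise FileNotFoundError(
            f"no frame meshes matching {config.frame_pattern!r} in {input_dir}"
        )
    landmarks_path = _resolve(config, "landmarks_path", "landmarks.csv")
    aspects_path = _resolve(config, "aspects_path", "aspects.json")
    if landmarks_path is None or aspects_path is None:
        raise FileNotFoundError("landmarks.csv and aspects.json sidecars are required")
    landmarks = _io.read_landmarks(landmarks_path)
    aspects_raw = _io.read_aspects(aspects_path)

    medial = fit_aspect_circle(aspects_raw["medial_rim"], "medial")
    lateral = fit_aspect_circle(aspects_raw["lateral_rim"], "lateral")
    humerus_path = _resolve(config, "humerus_path", "humerus.ply")
    humerus_mesh = _io.read_mesh(humerus_path) if humerus_path else None
    frame = build_frame(
        medial,
        lateral,
        aspects_raw["shaft_dir"],
        aspects_raw["posterior_hint"],
        humerus_mesh,
        side=config.side,
    )
    logger.info("humerus frame origin %s", np.round(frame.origin, 3))

    est_cfg = EstimatorConfig(
        offset_spacing=config.offset_spacing,
        offset_count=config.offset_count,
        lateral_hint=frame.X,
    )
    axes: dict[int, RotationAxis] = {}
    ulna_planes: dict[int, Plane] = {}
    failed: dict[int, str] = {}
    for i, path in enumerate(mesh_paths):
        if i not in landmarks:
            failed[i] = "no landmarks for frame"
            continue
        try:
            mesh = _io.read_mesh(path)
            axis = estimate_instantaneous_axis(mesh, landmarks[i], est_cfg, frame_index=i)
            axes[i] = axis
            ulna_planes[i] = ulna_coronal_plane(mesh, axis.point, axis.direction)
            logger.info(
                "frame %d axis dir %s rms %.4f mm", i, np.round(axis.direction, 4),
                axis.rms_residual,
            )
        except (AxisEstimationError, ValueError) as exc:
            failed[i] = str(exc)
            logger.warning("frame %d failed: %s", i, exc)
    if not axes:
        raise AxisEstimationError("all frames failed axis estimation")

    humeral_plane = Plane(point=frame.origin, normal=frame.Z)
    ok_frames = sorted(axes)
    flexion_vals = flexion_sequence([ulna_planes[i] for i in ok_frames], humeral_plane, frame.X)
    flexion = {i: float(v) for i, v in zip(ok_frames, flexion_vals)}

    inter_rows, angle_rows = [], []
    for i in ok_frames:
        ang = axis_angles(axes[i], frame)
        angle_rows.append(
            {
                "frame": i,
                "flexion_deg": flexion[i],
                "coronal_deg": ang.coronal_deg,
                "horizontal_deg": ang.horizontal_deg,
                "coronal_signed_deg": ang.coronal_signed_deg,
                "horizontal_signed_deg": ang.horizontal_signed_deg,
            }
        )
        for aspect in (medial, lateral):
            inter = make_intersection(
                axes[i], frame, aspect, lateral_reference=config.lateral_reference
            )
            inter_rows.append(
                {
                    "frame": i,
                    "flexion_deg": flexion[i],
                    "side": aspect.side,
                    "x": inter.point[0],
                    "y": inter.point[1],
                    "z": inter.point[2],
                    "y_pct": inter.y_pct,
                    "z_pct": inter.z_pct,
                    "quadrant": inter.quadrant,
                    "tie": inter.tie,
                }
            )
    intersections = pd.DataFrame(inter_rows)
    angles = pd.DataFrame(angle_rows)
    window = isometric_window(intersections, config.isometric_threshold_pct, flexion)

    trends: dict[str, TrendResult] = {}
    med = intersections[intersections["side"] == "medial"]
    lat = intersections[intersections["side"] == "lateral"]
    if len(med) >= 3:
        trends["medial_z_vs_flexion"] = linear_trend(med["flexion_deg"], med["z_pct"])
        trends["medial_y_vs_z"] = linear_trend(med["z_pct"], med["y_pct"])
    if len(lat) >= 3:
        trends["lateral_z_vs_flexion"] = linear_trend(lat["flexion_deg"], lat["z_pct"])
        trends["lateral_y_vs_z"] = linear_trend(lat["z_pct"], lat["y_pct"])

    summaries = {
        "coronal_deg": circular_or_linear_summary(angles["coronal_deg"]),
        "horizontal_deg": circular_or_linear_summary(angles["horizontal_deg"]),
        "flexion_deg": circular_or_linear_summary(angles["flexion_deg"]),
    }

    result = PipelineResult(
        frame=frame,
        axes=axes,
        flexion_deg=flexion,
        intersections=intersections,
        angles=angles,
        window=window,
        trends=trends,
        summaries=summaries,
        failed_frames=failed,
        n_frames_total=len(mesh_paths),
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    axis_rows = [
        {
            "frame": i,
            "flexion_deg": result.flexion_deg[i],
            "px": a.point[0],
            "py": a.point[1],
            "pz": a.point[2],
            "dx": a.direction[0],
            "dy": a.direction[1],
            "dz": a.direction[2],
            "rms_residual": a.rms_residual,
        }
        for i, a in sorted(result.axes.items())
    ]
    pd.DataFrame(axis_rows).to_csv(out / "axes.csv", index=False)
    diag_rows = [
        {
            "frame": i,
            "offset_index": k,
            "radius": fit.radius,
            "rms_residual": fit.rms_residual,
            "n_points": fit.n_points,
            "arc_extent_deg": fit.arc_extent_deg,
        }
        for i, a in sorted(result.axes.items())
        for k, fit in enumerate(a.circle_fits)
    ]
    pd.DataFrame(diag_rows).to_csv(out / "curve_diagnostics.csv", index=False)
    result.intersections.to_csv(out / "intersections.csv", index=False)
    result.angles.to_csv(out / "angles.csv", index=False)
    window_payload = {
        "threshold_pct": result.window.threshold_pct,
        "selected_frames": list(result.window.selected_frames),
        "flexion_range": list(result.window.flexion_range)
        if result.window.flexion_range
        else None,
    }
    (out / "window.json").write_text(json.dumps(window_payload, indent=1))
    summary = {
        "frame": {
            "origin": result.frame.origin.tolist(),
            "X": result.frame.X.tolist(),
            "Y": result.frame.Y.tolist(),
            "Z": result.frame.Z.tolist(),
        },
        "trends": {
            name: dataclasses.asdict(t) for name, t in result.trends.items()
        },
        "summaries": {
            name: dict(zip(("mean", "sd", "min", "max"), vals))
            for name, vals in result.summaries.items()
        },
        "failed_frames": result.failed_frames,
        "exit_code": result.exit_code,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    if config.make_plots:
        _plot_intersections(result.intersections, out)


def _plot_intersections(intersections: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for side in ("medial", "lateral"):
        df = intersections[intersections["side"] == side]
        if df.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(df["z_pct"], df["y_pct"], c=df["flexion_deg"], cmap="viridis", s=25)
        fig.colorbar(sc, ax=ax, label="flexion (deg)")
        circle = plt.Circle((0, 0), 100, fill=False, color="gray", lw=1)
        ax.add_patch(circle)
        ax.axhline(0, color="gray", lw=0.5)
        ax.axvline(0, color="gray", lw=0.5)
        ax.set_xlabel("z / aspect radius (%), posterior >")
        ax.set_ylabel("y / aspect radius (%), superior >")
        ax.set_title(f"{side} aspect pierce points")
        ax.set_aspect("equal")
        fig.tight_layout()
        fig.savefig(out / f"intersections_{side}.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixture(preset: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete synthetic fixture for one of the named presets.

    fixed_axis: pure hinge about the transcondylar axis (ground-truth axis
    identical across frames).  drifting_axis: the axis tilts and migrates
    with flexion (unsigned horizontal angle sweeping ~0 -> ~47 deg).
    noisy: fixed axis plus 0.2 mm Gaussian vertex noise (seeded).
    """
    from . import synthetic_data as synth

    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    params = synth.ElbowParams()
    humerus_mesh, humerus_truth = synth.make_distal_humerus(params)
    ulna = synth.make_proximal_ulna(params)
    if preset == "drifting_axis":
        traj = synth.drifting_axis_trajectory(params)
    else:
        traj = synth.fixed_axis_trajectory()
    meshes, landmarks, truth = synth.pose_sequence(ulna, traj, humerus_truth)
    if preset == "noisy":
        seeds = np.random.SeedSequence(seed).generate_state(len(meshes))
        meshes = [
            synth.add_vertex_noise(m, sigma=0.2, seed=int(s % (2**31)))
            for m, s in zip(meshes, seeds)
        ]
    return synth.write_fixture(
        out_dir, meshes, truth, landmarks=landmarks, humerus_mesh=humerus_mesh
    )
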