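"""Real-time guidance: tip localization, distance readout and insertion loop.

The insertion loop emulates the intraprocedural workflow: at every step the
patient and handle marker clusters are observed by the camera, both poses
are estimated, the planning-scan fiducial centroids are registered to the
tracked patient markers, and the displayed tip-to-target distance drives an
idealized operator that steps the needle toward the displayed target until
the displayed distance reaches the stop tolerance.

Internal targets are never re-imaged intra-procedure; their displayed
position comes solely from the planning scan mapped through the live
registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .camera import CameraModel, Observation2D, default_camera, estimate_pose, project
from .ctproc import ComponentClass, segment, target_centre as _segmented_centre, extract_marker_frame
from .geometry import FiducialSet, Frame, RigidTransform, register_rigid
from .respiration import BreathingMode, RespiratoryModel, displacement, sample_phase
from .scene import (
    FIDUCIAL_BAND,
    TARGET_VALUE_STEP,
    NeedleAssembly,
    SceneSpec,
    voxelize,
)

__all__ = [
    "NoiseConfig",
    "RespirationConfig",
    "ControllerConfig",
    "ScenePlan",
    "GuidanceReadout",
    "InsertionResult",
    "needle_tip",
    "tip_to_target",
    "overlay_points",
    "plan_scene",
    "simulate_insertion",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise magnitudes of the tracking chain."""

    fiducial_sigma_mm: float = 0.5
    pixel_sigma_px: float = 0.5

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0)


@dataclass(frozen=True)
class RespirationConfig:
    model: RespiratoryModel | None = None
    mode: BreathingMode = BreathingMode.GATED


@dataclass(frozen=True)
class ControllerConfig:
    """Idealized operator: straight steps toward the displayed target."""

    step_mm: float = 5.0
    stop_tolerance_mm: float = 0.5
    max_steps: int = 500
    max_consecutive_skips: int = 20


@dataclass
class ScenePlan:
    """Pre-treatment processing products: segmented marker and target centres."""

    scene: SceneSpec
    spacing_mm: float
    fiducial_centroids: FiducialSet  # CT frame, labels matching the scene's tags
    target_centres: dict[str, np.ndarray]


def needle_tip(handle_pose: RigidTransform, assembly: NeedleAssembly) -> np.ndarray:
    """Tip position: the fixed handle-frame offset mapped through the pose."""
    return handle_pose.apply(np.asarray(assembly.tip_offset, dtype=float))


def tip_to_target(tip: Sequence[float], centre: Sequence[float]) -> float:
    """Euclidean tip-to-target-centre distance (mm) — the accuracy quantity."""
    return float(np.linalg.norm(np.asarray(tip, float) - np.asarray(centre, float)))


def overlay_points(
    camera: CameraModel, patient_pose_estimate: RigidTransform, ct_points: Sequence
) -> np.ndarray:
    """Pixel coordinates at which CT-frame points are drawn over the video."""
    pts = np.atleast_2d(np.asarray(ct_points, dtype=float))
    if pts.size == 0:
        return np.zeros((0, 2))
    return project(camera, patient_pose_estimate.apply(pts))


def plan_scene(scene: SceneSpec, spacing: float | None = None) -> ScenePlan:
    """Voxelize and segment a scene: the pre-treatment imaging stage.

    Fiducial components are matched to the scene's ground-truth tags by
    nearest centroid; every tag must be recovered exactly once.
    """
    spacing = float(spacing if spacing is not None else scene.config.spacing_mm)
    volume = voxelize(scene, spacing)

    fid_map = segment(volume, *FIDUCIAL_BAND, component_class=ComponentClass.FIDUCIAL)
    truth = scene.fiducial_set()
    if fid_map.n_components != len(truth):
        raise RuntimeError(
            f"segmentation recovered {fid_map.n_components} fiducials, "
            f"expected {len(truth)}"
        )
    centroids = np.array(
        [
            extract_marker_frame(fid_map, lab, volume).centroid
            for lab in range(1, fid_map.n_components + 1)
        ]
    )
    # nearest-centroid correspondence with ground-truth labels
    order = []
    for true_pt in truth.points:
        d = np.linalg.norm(centroids - true_pt, axis=1)
        j = int(np.argmin(d))
        if d[j] > np.sqrt(3.0) * spacing or j in order:
            raise RuntimeError("ambiguous fiducial correspondence during planning")
        order.append(j)
    fiducial_centroids = FiducialSet(centroids[order], list(truth.labels), Frame.CT)

    centres: dict[str, np.ndarray] = {}
    for label in scene.target_labels:
        value = scene.target_intensity(label)
        tgt_map = segment(
            volume,
            value - TARGET_VALUE_STEP / 2.0,
            value + TARGET_VALUE_STEP / 2.0,
            min_size=1,
            component_class=ComponentClass.TARGET,
        )
        if tgt_map.n_components != 1:
            raise RuntimeError(
                f"target {label}: expected 1 component, found {tgt_map.n_components}"
            )
        centres[label] = _segmented_centre(tgt_map, 1, volume)
    return ScenePlan(scene, spacing, fiducial_centroids, centres)


@dataclass
class GuidanceReadout:
    """One guidance display update."""

    step: int
    phase: float
    displayed_tip_ct: np.ndarray
    target_centre_ct: np.ndarray
    displayed_distance_mm: float
    true_tip_world: np.ndarray
    true_distance_mm: float


@dataclass
class InsertionResult:
    trajectory: list[GuidanceReadout]
    final_true_error_mm: float
    steps: int
    hit: bool
    skipped_steps: int = 0
    target_label: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "target": self.target_label,
                "final_true_error_mm": self.final_true_error_mm,
                "steps": self.steps,
                "hit": self.hit,
                "skipped_steps": self.skipped_steps,
                "final_displayed_distance_mm": self.trajectory[-1].displayed_distance_mm,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    def trajectory_frame(self, path: str | Path | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "step": [r.step for r in self.trajectory],
                "phase": [r.phase for r in self.trajectory],
                "displayed_distance_mm": [r.displayed_distance_mm for r in self.trajectory],
                "true_error_mm": [r.true_distance_mm for r in self.trajectory],
            }
        )
        if path is not None:
            df.to_csv(path, index=False)
        return df


def _observe_points(
    camera: CameraModel,
    pts_world: np.ndarray,
    labels: list[str],
    sigma_px: float,
    rng: np.random.Generator,
) -> Observation2D:
    px = project(camera, pts_world)
    if sigma_px > 0:
        px = px + rng.normal(0.0, sigma_px, size=px.shape)
    return Observation2D(px, labels, sigma_px)


def simulate_insertion(
    scene: SceneSpec,
    camera: CameraModel | None = None,
    noise: NoiseConfig | None = None,
    respiration: RespirationConfig | None = None,
    controller: ControllerConfig | None = None,
    seed: int = 0,
    target: str | None = None,
    plan: ScenePlan | None = None,
) -> InsertionResult:
    """Run one guided insertion; see the module docstring for the loop.

    A *plan* (the expensive voxelize-and-segment stage) may be supplied to
    amortize it across repetitions; it must belong to the same scene.
    """
    noise = noise or NoiseConfig()
    respiration = respiration or RespirationConfig()
    controller = controller or ControllerConfig()
    plan = plan or plan_scene(scene)
    target = target or scene.target_labels[0]

    rng = np.random.default_rng(seed)
    # independent stream: phase sampling must not perturb the noise draws,
    # so zero-amplitude FREE runs reproduce GATED runs bit for bit
    phase_rng = np.random.default_rng([seed, 0x9E3779B9])
    T_pat = scene.patient_pose
    R_pat = T_pat.rotation

    truth_fids = scene.fiducial_set()
    ct_fids = plan.fiducial_centroids
    c_seg = plan.target_centres[target]
    c_true = scene.target_centre(target)
    assembly = scene.needle
    tip_offset = np.asarray(assembly.tip_offset, dtype=float)

    if camera is None:
        skin_top = float(T_pat.apply(truth_fids.points)[:, 2].max())
        camera = default_camera(scene.config.camera_distance_mm, skin_height_mm=skin_top)

    entry_world = T_pat.apply(np.asarray(scene.entry_points[target], dtype=float))
    handle_R = np.eye(3)
    handle_pose = RigidTransform(handle_R, entry_world - handle_R @ tip_offset)

    model = respiration.model
    mode = respiration.mode
    trajectory: list[GuidanceReadout] = []
    skipped = 0
    consecutive_skips = 0
    hit = False
    warm_patient: RigidTransform | None = None
    warm_handle: RigidTransform | None = None

    for step in range(controller.max_steps):
        phase = (
            sample_phase(mode, phase_rng, model.reference_phase)
            if model is not None
            else 0.0
        )
        if model is not None:
            d_target = R_pat @ displacement(model, "target", phase)
            d_skin = R_pat @ displacement(model, "skin", phase)
        else:
            d_target = d_skin = np.zeros(3)

        # (2)-(3) observe both marker clusters and estimate their poses
        marker_world = T_pat.apply(truth_fids.points) + d_skin
        obs_patient = _observe_points(
            camera, marker_world, list(ct_fids.labels), noise.pixel_sigma_px, rng
        )
        est_patient = estimate_pose(obs_patient, ct_fids, camera, initial_pose=warm_patient)
        obs_handle = _observe_points(
            camera,
            handle_pose.apply(assembly.handle_layout.points),
            list(assembly.handle_layout.labels),
            noise.pixel_sigma_px,
            rng,
        )
        est_handle = estimate_pose(
            obs_handle, assembly.handle_layout, camera, initial_pose=warm_handle
        )
        if not (est_patient.converged and est_handle.converged):
            warm_patient = warm_handle = None
            skipped += 1
            consecutive_skips += 1
            if consecutive_skips > controller.max_consecutive_skips:
                raise RuntimeError(
                    f"pose estimation failed {consecutive_skips} consecutive times "
                    f"at step {step} (target {target}, seed {seed})"
                )
            continue
        consecutive_skips = 0
        warm_patient = est_patient.pose
        warm_handle = est_handle.pose

        # (4) register planning-scan centroids to the tracked marker positions
        tracked_pts = est_patient.pose.apply(ct_fids.points)
        if noise.fiducial_sigma_mm > 0:
            tracked_pts = tracked_pts + rng.normal(
                0.0, noise.fiducial_sigma_mm, size=tracked_pts.shape
            )
        reg = register_rigid(
            ct_fids, FiducialSet(tracked_pts, list(ct_fids.labels), Frame.TRACKER)
        )

        # (5) displayed tip and distance
        tip_world_est = needle_tip(est_handle.pose, assembly)
        tip_ct = reg.transform.inverse().apply(tip_world_est)
        displayed = tip_to_target(tip_ct, c_seg)

        true_tip = needle_tip(handle_pose, assembly)
        true_target_world = T_pat.apply(c_true) + d_target
        true_dist = tip_to_target(true_tip, true_target_world)
        trajectory.append(
            GuidanceReadout(
                step=step,
                phase=phase,
                displayed_tip_ct=tip_ct,
                target_centre_ct=c_seg,
                displayed_distance_mm=displayed,
                true_tip_world=true_tip,
                true_distance_mm=true_dist,
            )
        )
        if displayed <= controller.stop_tolerance_mm:
            hit = True
            break

        # (6) step the true handle toward the displayed target
        advance = min(controller.step_mm, displayed)
        direction_world = reg.transform.rotation @ ((c_seg - tip_ct) / displayed)
        handle_pose = RigidTransform(
            handle_pose.rotation, handle_pose.translation + advance * direction_world
        )

    if not trajectory:
        raise RuntimeError("insertion produced no guidance readouts")
    return InsertionResult(
        trajectory=trajectory,
        final_true_error_mm=trajectory[-1].true_distance_mm,
        steps=len(trajectory),
        hit=hit,
        skipped_steps=skipped,
        target_label=target,
    )
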