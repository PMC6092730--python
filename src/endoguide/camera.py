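"""Pinhole-camera simulation and marker-cluster pose estimation.

Marker *detection* is simulated (exact projection plus Gaussian pixel
noise), which isolates the pose-estimation mathematics from any rendering
concern.  Pose estimation minimizes the reprojection error with iterative
nonlinear least squares, initialized from a homography decomposition for
(near-)planar layouts or a direct linear transform otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import FiducialSet, RigidTransform

__all__ = [
    "BehindCameraError",
    "InsufficientDataError",
    "CameraModel",
    "Observation2D",
    "PoseEstimate",
    "project",
    "observe",
    "estimate_pose",
    "default_camera",
]

_PLANARITY_RATIO = 0.12  # sigma_3 / sigma_1 below which a layout is near-planar


class BehindCameraError(ValueError):
    """A point has non-positive depth in the camera frame."""


class InsufficientDataError(ValueError):
    """Fewer than 4 point correspondences."""


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera.

    ``pose`` maps world coordinates into the camera frame (z forward).
    """

    focal_px: float = 1500.0
    principal_point: tuple[float, float] = (2000.0, 1500.0)
    image_size: tuple[int, int] = (4000, 3000)
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError("focal length must be positive")
        cx, cy = self.principal_point
        w, h = self.image_size
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValueError("principal point must lie inside the image")

    def intrinsic_matrix(self) -> np.ndarray:
        cx, cy = self.principal_point
        return np.array([[self.focal_px, 0, cx], [0, self.focal_px, cy], [0, 0, 1.0]])


def default_camera(
    distance_mm: float = 400.0, skin_height_mm: float = 0.0, focal_px: float = 1500.0
) -> CameraModel:
    """Camera looking straight down from ``distance_mm`` above ``skin_height_mm``."""
    R = np.diag([1.0, -1.0, -1.0])  # world +z maps to camera -z
    centre = np.array([0.0, 0.0, skin_height_mm + distance_mm])
    pose = RigidTransform(R, -R @ centre)
    return CameraModel(focal_px=focal_px, pose=pose)


def project(camera: CameraModel, pts_world: Sequence) -> np.ndarray:
    """Perspective projection u = f x/z + cx, v = f y/z + cy (pixels)."""
    pts = np.atleast_2d(np.asarray(pts_world, dtype=float))
    cam = camera.pose.apply(pts)
    z = cam[:, 2]
    if np.any(z <= 1e-9):
        raise BehindCameraError("point(s) at non-positive depth")
    cx, cy = camera.principal_point
    return np.column_stack(
        [camera.focal_px * cam[:, 0] / z + cx, camera.focal_px * cam[:, 1] / z + cy]
    )


@dataclass
class Observation2D:
    """Labelled pixel observations of a marker cluster."""

    points: np.ndarray
    labels: list[str]
    noise_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("observation points must be 2D")
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("observation points must be finite")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "points_px": self.points.tolist(),
                "labels": list(self.labels),
                "noise_sigma_px": self.noise_sigma_px,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def observe(
    camera: CameraModel,
    layout: FiducialSet,
    true_pose: RigidTransform,
    sigma_px: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Observation2D:
    """Project a posed layout and add independent Gaussian pixel noise."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    px = project(camera, true_pose.apply(layout.points))
    if sigma_px > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        px = px + rng.normal(0.0, sigma_px, size=px.shape)
    return Observation2D(px, list(layout.labels), sigma_px)


@dataclass
class PoseEstimate:
    """Object-frame -> world pose with reprojection diagnostics."""

    pose: RigidTransform
    reprojection_rms_px: float
    converged: bool
    initial_rms_px: float = np.nan

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "matrix_4x4_row_major": self.pose.as_matrix().ravel().tolist(),
                "reprojection_rms_px": self.reprojection_rms_px,
                "converged": self.converged,
                "initial_rms_px": self.initial_rms_px,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _rms(residual: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum(residual.reshape(-1, 2) ** 2, axis=1))))


def _project_cam(K: np.ndarray, pts_cam: np.ndarray) -> np.ndarray:
    z = pts_cam[:, 2]
    return np.column_stack(
        [K[0, 0] * pts_cam[:, 0] / z + K[0, 2], K[1, 1] * pts_cam[:, 1] / z + K[1, 2]]
    )


def _homography_candidates(
    obj: np.ndarray, px: np.ndarray, K: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Object->camera candidates from a best-fit-plane homography.

    Returns up to two (R, t) candidates (the classical planar two-fold
    ambiguity); both are screened for positive depths.
    """
    centroid = obj.mean(axis=0)
    _, _, vt = np.linalg.svd(obj - centroid)
    basis = vt[:2]  # in-plane
    plane_uv = (obj - centroid) @ basis.T

    # normalized DLT homography plane (u,v,1) -> pixel
    src = np.column_stack([plane_uv, np.ones(len(obj))])
    rows = []
    for (u, v, w), (x, y) in zip(src, px):
        rows.append([u, v, w, 0, 0, 0, -x * u, -x * v, -x * w])
        rows.append([0, 0, 0, u, v, w, -y * u, -y * v, -y * w])
    _, _, vh = np.linalg.svd(np.asarray(rows))
    H = vh[-1].reshape(3, 3)

    A = np.linalg.inv(K) @ H
    scale = np.sqrt(np.linalg.norm(A[:, 0]) * np.linalg.norm(A[:, 1]))
    if scale < 1e-12:
        return []
    candidates = []
    for sign in (1.0, -1.0):
        B = sign * A / scale
        r1, r2, t = B[:, 0], B[:, 1], B[:, 2]
        r3 = np.cross(r1, r2)
        Rp = np.column_stack([r1, r2, r3])
        u, _, vt2 = np.linalg.svd(Rp)
        Rp = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt2))]) @ vt2
        M = np.vstack([basis, np.cross(basis[0], basis[1])])
        R = Rp @ M
        tt = t - R @ centroid
        if np.all((obj @ R.T + tt)[:, 2] > 0):
            candidates.append((R, tt))
    return candidates


def _dlt_candidate(
    obj: np.ndarray, px: np.ndarray, K: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Calibrated direct linear transform (n >= 6, non-planar)."""
    norm = (px - K[:2, 2]) / K[0, 0]
    rows = []
    for (X, Y, Z), (mx, my) in zip(obj, norm):
        rows.append([X, Y, Z, 1, 0, 0, 0, 0, -mx * X, -mx * Y, -mx * Z, -mx])
        rows.append([0, 0, 0, 0, X, Y, Z, 1, -my * X, -my * Y, -my * Z, -my])
    _, _, vh = np.linalg.svd(np.asarray(rows))
    P = vh[-1].reshape(3, 4)
    scale = np.cbrt(np.abs(np.linalg.det(P[:, :3])))
    if scale < 1e-12:
        return []
    P = P / scale
    if np.mean((obj @ P[:, :3].T + P[:, 3])[:, 2]) < 0:
        P = -P
    u, _, vt = np.linalg.svd(P[:, :3])
    R = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    t = P[:, 3]
    if np.all((obj @ R.T + t)[:, 2] > 0):
        return [(R, t)]
    return []


def estimate_pose(
    obs: Observation2D,
    layout: FiducialSet,
    camera: CameraModel,
    max_iterations: int = 100,
    initial_pose: RigidTransform | None = None,
) -> PoseEstimate:
    """Estimate the rigid pose of a marker layout from its 2D observation.

    Minimizes the sum of squared reprojection errors over the rigid pose.
    The planar two-fold ambiguity is resolved by refining both homography
    decompositions and preferring the solution whose layout normal faces
    the camera, ties broken by lower reprojection RMS.

    ``initial_pose`` (object -> world, e.g. the previous tracking frame)
    replaces the linear initialization, which speeds up continuous tracking.
    """
    if len(obs.labels) < 4:
        raise InsufficientDataError("pose estimation requires >= 4 points")
    lay = layout.reordered(obs.labels)
    if lay.is_degenerate():
        raise InsufficientDataError("layout must be non-collinear")
    obj = lay.points
    px = obs.points
    K = camera.intrinsic_matrix()

    centred = obj - obj.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if initial_pose is not None:
        warm = camera.pose.compose(initial_pose)
        candidates = [(warm.rotation, warm.translation)]
    elif len(obj) >= 6 and s[2] >= _PLANARITY_RATIO * s[0]:
        candidates = _dlt_candidate(obj, px, K)
        if not candidates:
            candidates = _homography_candidates(obj, px, K)
    else:
        candidates = _homography_candidates(obj, px, K)
    if not candidates:
        raise BehindCameraError("no pose candidate places the layout in front of the camera")

    f = camera.focal_px

    def residual(params: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        cam_pts = obj @ R.T + params[3:]
        z = np.maximum(cam_pts[:, 2], 1e-6)
        cam_pts = np.column_stack([cam_pts[:, 0], cam_pts[:, 1], z])
        return (_project_cam(K, cam_pts) - px).ravel()

    def jacobian(params: np.ndarray) -> np.ndarray:
        # d(pixel)/d(rotvec, t); rotvec uses the right Jacobian of SO(3)
        w = params[:3]
        R = Rotation.from_rotvec(w).as_matrix()
        theta = np.linalg.norm(w)
        W = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        if theta < 1e-12:
            Jr = np.eye(3)
        else:
            Jr = (
                np.eye(3)
                - (1 - np.cos(theta)) / theta**2 * W
                + (theta - np.sin(theta)) / theta**3 * (W @ W)
            )
        cam_pts = obj @ R.T + params[3:]
        n = len(obj)
        J = np.empty((2 * n, 6))
        for i in range(n):
            X = obj[i]
            x, y, z = cam_pts[i]
            z = max(z, 1e-6)
            d_uv_cam = np.array([[f / z, 0.0, -f * x / z**2], [0.0, f / z, -f * y / z**2]])
            Xx = np.array([[0, -X[2], X[1]], [X[2], 0, -X[0]], [-X[1], X[0], 0]])
            d_cam = np.hstack([-R @ Xx @ Jr, np.eye(3)])
            J[2 * i : 2 * i + 2] = d_uv_cam @ d_cam
        return J

    # noisy observations do not warrant machine-precision convergence
    tol = 1e-15 if obs.noise_sigma_px == 0 else 1e-11
    refined = []
    for R0, t0 in candidates:
        x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(), t0])
        init_rms = _rms(residual(x0))
        sol = least_squares(
            residual,
            x0,
            jac=jacobian,
            method="lm",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=max_iterations * 8,
        )
        rms = _rms(sol.fun)
        R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
        t = sol.x[3:]
        # does the layout's best-fit-plane normal face the camera?
        _, _, vt = np.linalg.svd(centred)
        n_cam = R @ vt[2]
        centre_cam = R @ obj.mean(axis=0) + t
        facing = bool(n_cam @ centre_cam < 0)
        converged = bool(sol.status > 0 and rms <= init_rms + 1e-12)
        refined.append((rms, facing, R, t, converged, init_rms))

    refined.sort(key=lambda item: item[0])
    best = refined[0]
    if len(refined) > 1 and refined[1][0] <= best[0] * (1 + 1e-6) + 1e-9:
        # numerically tied (exact planar ambiguity): prefer facing normal
        facing_sols = [r for r in refined[:2] if r[1]]
        if facing_sols:
            best = facing_sols[0]
    rms, _, R, t, converged, init_rms = best
    object_to_camera = RigidTransform(R, t)
    object_to_world = camera.pose.inverse().compose(object_to_camera)
    return PoseEstimate(object_to_world, rms, converged, init_rms)
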