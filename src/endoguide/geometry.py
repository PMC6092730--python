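"""Rigid 3D geometry: transforms, labelled point sets and point-set registration.

Everything downstream (scene synthesis, tracking, guidance) moves points
between coordinate frames with :class:`RigidTransform` and aligns fiducial
configurations with :func:`register_rigid`, the closed-form least-squares
(SVD / Kabsch) solution with reflection correction.

Units are millimetres throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "RigidTransform",
    "FiducialSet",
    "RegistrationResult",
    "CorrespondenceError",
    "DegenerateConfigurationError",
    "apply_transform",
    "register_rigid",
    "match_correspondence",
    "target_registration_error",
    "random_rigid_transform",
]

_ORTHONORMAL_TOL = 1e-9
# relative singular-value floor separating flat/collinear configurations
_DEGENERACY_RTOL = 1e-6


class Frame(str, Enum):
    """Coordinate frame a fiducial set is expressed in."""

    CT = "CT"
    TRACKER = "TRACKER"


class CorrespondenceError(ValueError):
    """Label sets of the two point sets do not correspond."""


class DegenerateConfigurationError(ValueError):
    """Point configuration is collinear (or smaller than 3 points)."""


def _as_points(pts: Iterable) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of points, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t``.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal matrix with determinant +1.
    translation : (3,) ndarray
        Offset in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.max(np.abs(R.T @ R - np.eye(3))) >= 1e-9:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) >= 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis: Sequence[float], angle_rad: float, translation: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)
        # re-orthonormalize to keep the constructor's 1e-9 invariant honest
        u, _, vt = np.linalg.svd(R)
        return cls(u @ vt, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        m = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, pts: Iterable) -> np.ndarray:
        """Apply to one point or an (n, 3) stack of points."""
        arr = np.asarray(pts, dtype=float)
        single = arr.ndim == 1
        out = _as_points(arr) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def apply_transform(t: RigidTransform, pts: Iterable) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(pts)


@dataclass
class FiducialSet:
    """Ordered, labelled 3D fiducial points tagged with their frame."""

    points: np.ndarray
    labels: list[str]
    frame: Frame = Frame.CT

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        self.frame = Frame(self.frame)

    def __len__(self) -> int:
        return len(self.labels)

    def is_degenerate(self) -> bool:
        """True when < 3 points or the configuration is collinear.

        Collinearity test: the two smallest singular values of the centred
        point matrix must both exceed ``1e-6`` times the largest.
        """
        if len(self) < 3:
            return True
        centred = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        return not (s[1] > _DEGENERACY_RTOL * s[0])

    def reordered(self, labels: Sequence[str]) -> "FiducialSet":
        index = {l: i for i, l in enumerate(self.labels)}
        try:
            order = [index[l] for l in labels]
        except KeyError as exc:
            raise CorrespondenceError(f"label {exc} not present") from exc
        return FiducialSet(self.points[order], list(labels), self.frame)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "frame": self.frame.value,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FiducialSet":
        df = pd.read_csv(path)
        frames = df["frame"].unique()
        if len(frames) != 1:
            raise ValueError("fiducial CSV must contain a single frame tag")
        return cls(
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            df["label"].astype(str).tolist(),
            Frame(frames[0]),
        )


@dataclass
class RegistrationResult:
    """Outcome of a rigid point-set registration.

    ``fre`` is the root-mean-square residual over fiducials (mm).
    """

    transform: RigidTransform
    fre: float
    per_fiducial_residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "matrix_4x4_row_major": self.transform.as_matrix().ravel().tolist(),
            "fre_mm": float(self.fre),
            "per_fiducial_residuals_mm": np.asarray(self.per_fiducial_residuals).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationResult":
        payload = json.loads(Path(path).read_text())
        m = np.asarray(payload["matrix_4x4_row_major"], dtype=float).reshape(4, 4)
        return cls(
            RigidTransform.from_matrix(m),
            float(payload["fre_mm"]),
            np.asarray(payload["per_fiducial_residuals_mm"], dtype=float),
        )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit src -> dst (correspondence known)."""
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    H = (src - src_c).T @ (dst - dst_c)
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # reflection correction: constrain to a proper rotation
    D = np.diag([1.0, 1.0, d])
    R = vt.T @ D @ u.T
    t = dst_c - R @ src_c
    return RigidTransform(R, t)


def register_rigid(src: FiducialSet, dst: FiducialSet) -> RegistrationResult:
    """Least-squares rigid registration of *src* onto *dst*.

    Minimizes ``sum_i || T(src_i) - dst_i ||^2`` over proper rigid
    transforms, via SVD of the cross-covariance of the centred points with
    determinant sign correction.

    Raises
    ------
    CorrespondenceError
        If the two sets do not carry identical labels in identical order.
    DegenerateConfigurationError
        If either configuration has < 3 points or is collinear.
    """
    if src.labels != dst.labels:
        raise CorrespondenceError("source and destination labels must match in order")
    if src.is_degenerate() or dst.is_degenerate():
        raise DegenerateConfigurationError(
            "registration requires >= 3 non-collinear points in both sets"
        )
    transform = _kabsch(src.points, dst.points)
    residuals = np.linalg.norm(transform.apply(src.points) - dst.points, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(transform, fre, residuals)


def match_correspondence(src: FiducialSet, dst: FiducialSet) -> FiducialSet:
    """Exhaustive-permutation correspondence search (n <= 8).

    Returns *dst* reordered (and relabelled with src's labels) so that the
    rigid fit of ``src -> dst`` has minimal FRE.  Ties are broken by
    lexicographic permutation order.
    """
    n = len(src)
    if n != len(dst):
        raise CorrespondenceError("point counts differ")
    if n > 8:
        raise ValueError("exhaustive matching is limited to 8 points")
    best_perm = None
    best_fre = np.inf
    for perm in itertools.permutations(range(n)):
        candidate = dst.points[list(perm)]
        t = _kabsch(src.points, candidate)
        fre = float(np.sqrt(np.mean(np.sum((t.apply(src.points) - candidate) ** 2, axis=1))))
        if fre < best_fre - 1e-12:
            best_fre = fre
            best_perm = perm
    return FiducialSet(dst.points[list(best_perm)], list(src.labels), dst.frame)


def target_registration_error(
    reg: RegistrationResult, true_map: RigidTransform, probe: Sequence[float]
) -> float:
    """Distance between the estimated and true images of a probe point (mm)."""
    probe = np.asarray(probe, dtype=float)
    return float(np.linalg.norm(reg.transform.apply(probe) - true_map.apply(probe)))


def random_rigid_transform(
    rng: np.random.Generator, max_translation_mm: float = 100.0
) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix) + bounded translation."""
    A = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(A)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(q, t)
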