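"""Synthetic ground-truth scenes and CT-like voxelization.

Three scenarios are provided, mirroring the physical accuracy studies:

* ``anthro``  — trunk phantom (500 x 340 x 270 mm envelope) with five
  cylindrical bar targets and 30 square surface fiducials; bar centres are
  placed by least-squares 3D embedding of the published pairwise distances.
* ``porcine`` — body with three small point targets at depths 107.6 /
  123.7 / 92.5 mm below their entry points and 12 skin fiducials.
* ``cadaver`` — body with two spherical lesions (18 mm at 50.6 mm depth,
  30 mm at 91.2 mm depth) and 12 skin fiducials.

The body envelope is a superellipsoid — fiducial-on-surface and
target-depth semantics only need a smooth closed surface, not anatomy.
Target centres are snapped to the voxel grid of the configured spacing so
that voxelized solids are symmetric about their true centres and centroid
recovery is unbiased; entry points are placed depth mm straight above the
(snapped) centre, which leaves them within half a voxel of the envelope
surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from . import refdata
from .geometry import FiducialSet, Frame, RigidTransform

__all__ = [
    "INTENSITY",
    "FIDUCIAL_BAND",
    "TARGET_BAND",
    "TISSUE_BAND",
    "ConstructionError",
    "Superellipsoid",
    "SquareFiducial",
    "BarTarget",
    "PointTarget",
    "SphereLesion",
    "NeedleAssembly",
    "SceneConfig",
    "SceneSpec",
    "VoxelVolume",
    "embed_distances",
    "default_config",
    "build_anthropomorphic_scene",
    "build_porcine_scene",
    "build_cadaver_scene",
    "build_scene",
    "voxelize",
]

# HU-like intensity classes; chosen to make single-threshold segmentation
# unambiguous.  Each target additionally gets its own value inside the
# target band so that geometrically touching targets remain separable.
INTENSITY = {"air": -1000.0, "tissue": 40.0, "target": 300.0, "fiducial": 3000.0}
TARGET_VALUE_STEP = 20.0

FIDUCIAL_BAND = (2000.0, 4000.0)
TARGET_BAND = (250.0, 1500.0)
TISSUE_BAND = (0.0, 100.0)


class ConstructionError(ValueError):
    """Requested scene is geometrically infeasible."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superellipsoid:
    """Implicit solid |x/a|^p + |y/b|^p + |z/c|^p <= 1, centred at the origin."""

    semi_axes: tuple[float, float, float]
    exponent: float = 6.0

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        a = np.asarray(self.semi_axes, dtype=float)
        return np.sum(np.abs(pts / a) ** self.exponent, axis=1)

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Inside test; positive *margin* (mm) shrinks the solid."""
        a = np.asarray(self.semi_axes, dtype=float) - margin
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.sum(np.abs(pts / a) ** self.exponent, axis=1) <= 1.0

    def surface_z(self, x: float, y: float) -> float:
        """Height of the upper surface above (x, y)."""
        a, b, c = self.semi_axes
        rem = 1.0 - abs(x / a) ** self.exponent - abs(y / b) ** self.exponent
        if rem <= 0:
            raise ConstructionError(f"({x}, {y}) is outside the envelope footprint")
        return c * rem ** (1.0 / self.exponent)

    def normal(self, pt: Sequence[float]) -> np.ndarray:
        """Outward unit normal at a surface point."""
        a = np.asarray(self.semi_axes, dtype=float)
        p = self.exponent
        pt = np.asarray(pt, dtype=float)
        g = p / a * np.abs(pt / a) ** (p - 1) * np.sign(pt / a)
        return g / np.linalg.norm(g)


@dataclass(frozen=True)
class SquareFiducial:
    """Thin square radiopaque tag on the body surface."""

    centre: tuple[float, float, float]
    normal: tuple[float, float, float]
    in_plane_axis: tuple[float, float, float]
    edge: float = 35.0
    thickness: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        u = np.asarray(self.in_plane_axis, dtype=float)
        if abs(float(n @ u)) >= 1e-9:
            raise ValueError("in-plane axis must be perpendicular to the normal")
        if self.edge <= 0:
            raise ValueError("edge must be positive")

    def frame(self) -> np.ndarray:
        """Rows: in-plane u, in-plane v, normal."""
        n = np.asarray(self.normal, dtype=float)
        u = np.asarray(self.in_plane_axis, dtype=float)
        return np.stack([u, np.cross(n, u), n])


@dataclass(frozen=True)
class BarTarget:
    """Solid cylinder between two endpoints."""

    endpoint_a: tuple[float, float, float]
    endpoint_b: tuple[float, float, float]
    radius: float
    label: str

    @property
    def centre(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.endpoint_a) + np.asarray(self.endpoint_b))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.endpoint_b) - np.asarray(self.endpoint_a)))


@dataclass(frozen=True)
class PointTarget:
    """Small implanted marker, a prolate ellipsoid (full axes, mm)."""

    centre: tuple[float, float, float]
    extent: tuple[float, float] = (2.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.extent) <= 0:
            raise ValueError("extent must be positive")


@dataclass(frozen=True)
class SphereLesion:
    centre: tuple[float, float, float]
    diameter: float
    label: str


@dataclass(frozen=True)
class NeedleAssembly:
    """Tracked handle marker layout plus the fixed handle-to-tip offset."""

    handle_layout: FiducialSet
    tip_offset: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.handle_layout.is_degenerate():
            raise ValueError("handle layout must be >= 3 non-collinear points")
        norm = float(np.linalg.norm(np.asarray(self.tip_offset, dtype=float)))
        if abs(norm - refdata.NEEDLE_LENGTH_MM) >= 1e-9:
            raise ValueError(f"tip offset must have norm {refdata.NEEDLE_LENGTH_MM} mm")

    @classmethod
    def default(cls) -> "NeedleAssembly":
        # 40 x 40 mm marker square on top of the handle plus one point 20 mm
        # above its centre (non-coplanar, for robust pose estimation)
        pts = np.array(
            [
                [-20.0, -20.0, 0.0],
                [20.0, -20.0, 0.0],
                [20.0, 20.0, 0.0],
                [-20.0, 20.0, 0.0],
                [0.0, 0.0, 20.0],
            ]
        )
        layout = FiducialSet(pts, [f"H{i + 1}" for i in range(5)], Frame.TRACKER)
        return cls(layout, (0.0, 0.0, -refdata.NEEDLE_LENGTH_MM))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Scenario parameters (YAML-serializable)."""

    scenario: str
    envelope_semi_axes_mm: tuple[float, float, float]
    envelope_exponent: float = 6.0
    spacing_mm: float = 1.0
    n_fiducials: int = 12
    fiducial_edge_mm: float = 35.0
    fiducial_thickness_mm: float = 2.0
    n_bars: int = 0
    target_depths_mm: dict = field(default_factory=dict)
    lesions: dict = field(default_factory=dict)
    camera_distance_mm: float = 400.0
    patient_pose_axis: tuple[float, float, float] = (0.2, 1.0, 0.1)
    patient_pose_angle_deg: float = 4.0
    patient_pose_translation_mm: tuple[float, float, float] = (12.0, -8.0, 5.0)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in (
            "envelope_semi_axes_mm",
            "patient_pose_axis",
            "patient_pose_translation_mm",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_config(scenario: str) -> SceneConfig:
    if scenario == "anthro":
        return SceneConfig(
            scenario="anthro",
            envelope_semi_axes_mm=(250.0, 170.0, 135.0),
            n_fiducials=30,
            n_bars=5,
        )
    if scenario == "porcine":
        return SceneConfig(
            scenario="porcine",
            envelope_semi_axes_mm=(225.0, 150.0, 120.0),
            n_fiducials=12,
            target_depths_mm=dict(refdata.PORCINE_TARGET_DEPTHS_MM),
        )
    if scenario == "cadaver":
        return SceneConfig(
            scenario="cadaver",
            envelope_semi_axes_mm=(230.0, 160.0, 125.0),
            n_fiducials=12,
            lesions={k: dict(v) for k, v in refdata.CADAVER_LESIONS.items()},
        )
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# scene spec
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Ground-truth geometric description of one experimental scenario.

    All geometry is expressed in the CT frame; ``patient_pose`` maps CT
    coordinates into the world (tracker) frame.
    """

    name: str
    envelope: Superellipsoid | None
    fiducials: list[SquareFiducial]
    targets: list
    needle: NeedleAssembly
    patient_pose: RigidTransform
    entry_points: dict[str, tuple[float, float, float]]
    config: SceneConfig

    def fiducial_set(self) -> FiducialSet:
        pts = np.array([f.centre for f in self.fiducials])
        return FiducialSet(pts, [f.label for f in self.fiducials], Frame.CT)

    def target_centre(self, label: str) -> np.ndarray:
        for t in self.targets:
            if t.label == label:
                return np.asarray(t.centre, dtype=float)
        raise KeyError(label)

    @property
    def target_labels(self) -> list[str]:
        return [t.label for t in self.targets]

    def target_intensity(self, label: str) -> float:
        idx = self.target_labels.index(label)
        return INTENSITY["target"] + TARGET_VALUE_STEP * idx

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "envelope": None
            if self.envelope is None
            else {
                "semi_axes": list(self.envelope.semi_axes),
                "exponent": self.envelope.exponent,
            },
            "fiducials": [_jsonable(asdict(f)) for f in self.fiducials],
            "targets": [
                dict(kind=type(t).__name__, **_jsonable(asdict(t))) for t in self.targets
            ],
            "needle": {
                "handle_points": self.needle.handle_layout.points.tolist(),
                "handle_labels": list(self.needle.handle_layout.labels),
                "tip_offset": list(self.needle.tip_offset),
            },
            "patient_pose": self.patient_pose.as_matrix().tolist(),
            "entry_points": {k: list(v) for k, v in self.entry_points.items()},
            "config": _jsonable(asdict(self.config)),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# voxel volume
# ---------------------------------------------------------------------------


@dataclass
class VoxelVolume:
    """CT-like intensity grid with voxel-centre world convention.

    World coordinate of voxel index (i, j, k) is ``origin + (i, j, k) * spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_centre(self) -> np.ndarray:
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.spacing

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asanyarray(self.data), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        data = np.asanyarray(img.dataobj)
        return cls(data, np.diag(affine[:3, :3]).copy(), affine[:3, 3].copy())


# ---------------------------------------------------------------------------
# distance embedding
# ---------------------------------------------------------------------------


def embed_distances(
    pair_distances: dict[tuple[int, int], float], n: int = 5
) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Least-squares 3D embedding of pairwise distances.

    Classical multidimensional scaling followed by gradient refinement of
    ``sum (|xi - xj| - d_ij)^2``.  Returns centred positions (principal axes
    aligned to the coordinate axes, descending) and per-pair residuals
    (embedded minus requested distance, mm).  The result is deterministic.
    """
    D = np.zeros((n, n))
    for (i, j), d in pair_distances.items():
        D[i - 1, j - 1] = D[j - 1, i - 1] = d
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:3]
    X0 = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    iu = np.triu_indices(n, 1)

    def residual(x: np.ndarray) -> np.ndarray:
        P = x.reshape(n, 3)
        return np.linalg.norm(P[iu[0]] - P[iu[1]], axis=1) - D[iu]

    sol = least_squares(residual, X0.ravel(), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    P = sol.x.reshape(n, 3)
    P -= P.mean(axis=0)
    # rotate so principal axes (descending spread) align with x, y, z
    _, _, vt = np.linalg.svd(P, full_matrices=False)
    if np.linalg.det(vt) < 0:
        vt[2] = -vt[2]
    P = P @ vt.T
    # deterministic sign convention: first point has non-positive coordinates
    for axis in range(3):
        if P[0, axis] > 0:
            P[:, axis] = -P[:, axis]
    dist = np.linalg.norm(P[iu[0]] - P[iu[1]], axis=1)
    residuals = {
        (int(i + 1), int(j + 1)): float(d - D[i, j])
        for i, j, d in zip(iu[0], iu[1], dist)
    }
    return P, residuals


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _patient_pose(config: SceneConfig) -> RigidTransform:
    return RigidTransform.from_axis_angle(
        config.patient_pose_axis,
        np.deg2rad(config.patient_pose_angle_deg),
        config.patient_pose_translation_mm,
    )


def _snap(values: np.ndarray, spacing: float) -> np.ndarray:
    return np.round(np.asarray(values, dtype=float) / spacing) * spacing


def _place_surface_fiducials(
    envelope: Superellipsoid,
    n: int,
    edge: float,
    thickness: float,
    seed: int,
    spacing: float = 1.0,
) -> list[SquareFiducial]:
    """Quasi-uniform square tags on the upper envelope surface.

    Candidate (x, y) sites come from a golden-ratio lattice over the upper
    footprint; *n* sites are then chosen by greedy farthest-point selection
    (first site fixed by the seed), which keeps tags well separated.  Tag
    centres are snapped to the voxel lattice (at most spacing/2 off the
    surface) so that tags on the flat top rasterize symmetrically about
    their centre and centroid recovery is unbiased.
    """
    a, b, _ = envelope.semi_axes
    rng = np.random.default_rng(seed)
    m = 1024
    g = 1.32471795724474602596  # 2D quasi-random (plastic number) lattice
    alpha = np.array([1.0 / g, 1.0 / g**2])
    uv = (0.5 + np.arange(m)[:, None] * alpha) % 1.0
    xy = (uv - 0.5) * np.array([2 * 0.86 * a, 2 * 0.86 * b])
    # keep candidates on the gently sloped top (normal pointing well upward)
    keep = []
    for x, y in xy:
        rem = 1.0 - abs(x / a) ** envelope.exponent - abs(y / b) ** envelope.exponent
        if rem <= 0.2:
            continue
        z = envelope.surface_z(x, y)
        if envelope.normal((x, y, z))[2] >= 0.5:
            keep.append((x, y, z))
    cand = np.array(keep)
    if len(cand) < n:
        raise ConstructionError("not enough surface area for requested fiducial count")
    chosen = [int(rng.integers(len(cand)))]
    d2 = np.sum((cand - cand[chosen[0]]) ** 2, axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((cand - cand[nxt]) ** 2, axis=1))
    sites = cand[chosen]
    min_sep = np.sqrt(
        min(
            np.sum((sites[i] - sites[j]) ** 2)
            for i in range(n)
            for j in range(i + 1, n)
        )
    )
    if min_sep < edge * np.sqrt(2.0) * 1.02:
        raise ConstructionError(
            f"fiducials too crowded (min separation {min_sep:.1f} mm for {edge} mm tags)"
        )
    fids = []
    for k, (x, y, z) in enumerate(sites):
        nrm = envelope.normal((x, y, z))
        x, y, z = _snap(np.array([x, y, z]), spacing)
        u = np.array([1.0, 0.0, 0.0]) - nrm[0] * nrm
        if np.linalg.norm(u) < 1e-6:
            u = np.array([0.0, 1.0, 0.0]) - nrm[1] * nrm
        u /= np.linalg.norm(u)
        fids.append(
            SquareFiducial(
                centre=(float(x), float(y), float(z)),
                normal=tuple(nrm),
                in_plane_axis=tuple(u),
                edge=edge,
                thickness=thickness,
                label=f"F{k + 1:02d}",
            )
        )
    return fids


def _check_bar_inside(envelope: Superellipsoid, bar: BarTarget) -> None:
    a = np.asarray(bar.endpoint_a, dtype=float)
    b = np.asarray(bar.endpoint_b, dtype=float)
    axis = (b - a) / np.linalg.norm(b - a)
    # orthonormal frame around the axis
    u = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ts = np.linspace(0.0, 1.0, 21)
    angles = np.linspace(0.0, 2 * np.pi, 13)
    pts = [
        a + t * (b - a) + bar.radius * (np.cos(th) * u + np.sin(th) * v)
        for t in ts
        for th in angles
    ]
    if not np.all(envelope.contains(np.array(pts), margin=1.0)):
        raise ConstructionError(f"bar {bar.label} protrudes from the envelope")


_BAR_LENGTHS = {1: 450.0, 2: 300.0, 3: 200.0, 4: 160.0, 5: 160.0}
_BAR_RADII = {1: 10.0, 2: 10.0, 3: 10.0, 4: 15.0, 5: 15.0}
# Axis directions chosen so that the inter-axis clearance of the close bar
# cluster (centres 13.5-28 mm apart) is maximal: tilting bars 2 and 3 in the
# x-z plane makes their clearance to bar 1 equal to the full y-offset.
_S30, _C30 = np.sin(np.pi / 6), np.cos(np.pi / 6)
_BAR_DIRECTIONS = {
    1: np.array([1.0, 0.0, 0.0]),
    2: np.array([_C30, 0.0, _S30]),
    3: np.array([_C30, 0.0, -_S30]),
    4: np.array([1.0, 0.0, 0.0]),
    5: np.array([1.0, 0.0, 0.0]),
}


def build_anthropomorphic_scene(config: SceneConfig | None = None, seed: int = 0) -> SceneSpec:
    """Trunk phantom: five bars + 30 surface tags.

    Bar geometric centres come from the least-squares embedding of the ten
    published pairwise distances (snapped to the voxel grid); they cannot
    reproduce the measurements exactly because those are non-Euclidean.
    """
    config = config or default_config("anthro")
    if config.n_bars != 5:
        raise ConstructionError("the trunk scenario requires exactly 5 bars")
    envelope = Superellipsoid(config.envelope_semi_axes_mm, config.envelope_exponent)
    positions, _ = embed_distances(refdata.ANTHRO_REAL_DISTANCES_MM, n=5)
    # embedding axes: principal spread -> y, secondary -> x, residual -> z;
    # keeping the close cluster at one height makes the overlap chunks that
    # the non-Euclidean distances force sit on opposite sides of bar 2
    centres = positions[:, [1, 0, 2]]
    # shift so bar 1 (the 450 mm bar, oriented along x) is centred in x and
    # the cluster sits around mid-height
    centres[:, 0] -= centres[0, 0]
    centres[:, 1] -= centres[:, 1].mean()
    centres = _snap(centres, config.spacing_mm)
    bars = []
    for k in range(5):
        i = k + 1
        d = _BAR_DIRECTIONS[i]
        half = 0.5 * _BAR_LENGTHS[i] * d
        bar = BarTarget(
            endpoint_a=tuple(centres[k] - half),
            endpoint_b=tuple(centres[k] + half),
            radius=_BAR_RADII[i],
            label=f"Bar{i}",
        )
        _check_bar_inside(envelope, bar)
        bars.append(bar)
    fids = _place_surface_fiducials(
        envelope,
        config.n_fiducials,
        config.fiducial_edge_mm,
        config.fiducial_thickness_mm,
        seed,
        config.spacing_mm,
    )
    entry = {}
    for bar in bars:
        c = bar.centre
        entry[bar.label] = (float(c[0]), float(c[1]), float(envelope.surface_z(c[0], c[1])))
    return SceneSpec(
        name="anthro",
        envelope=envelope,
        fiducials=fids,
        targets=bars,
        needle=NeedleAssembly.default(),
        patient_pose=_patient_pose(config),
        entry_points=entry,
        config=config,
    )


def _depth_targets(
    envelope: Superellipsoid,
    depths: dict[str, float],
    spacing: float,
    make_target,
) -> tuple[list, dict]:
    """Place targets at exact depths below near-surface entry points."""
    c = envelope.semi_axes[2]
    n = len(depths)
    if n == 0:
        raise ConstructionError("at least one target is required")
    xs = np.linspace(-60.0, 60.0, n) if n > 1 else np.array([0.0])
    ys = np.array([20.0 * ((-1) ** k) for k in range(n)])
    targets, entries = [], {}
    for (label, depth), x, y in zip(depths.items(), xs, ys):
        if depth >= 2 * c:
            raise ConstructionError(f"target {label} depth {depth} exceeds body thickness")
        x, y = float(_snap(x, spacing)), float(_snap(y, spacing))
        z_surf = envelope.surface_z(x, y)
        z_tgt = float(_snap(z_surf - depth, spacing))
        centre = np.array([x, y, z_tgt])
        if not envelope.contains(centre, margin=2.0)[0]:
            raise ConstructionError(f"target {label} at depth {depth} falls outside the body")
        targets.append(make_target(label, (x, y, z_tgt)))
        entries[label] = (x, y, z_tgt + depth)
    return targets, entries


def build_porcine_scene(config: SceneConfig | None = None, seed: int = 0) -> SceneSpec:
    """Porcine-like body: three implanted point targets + 12 skin tags."""
    config = config or default_config("porcine")
    envelope = Superellipsoid(config.envelope_semi_axes_mm, config.envelope_exponent)
    depths = config.target_depths_mm or dict(refdata.PORCINE_TARGET_DEPTHS_MM)
    targets, entries = _depth_targets(
        envelope,
        depths,
        config.spacing_mm,
        lambda label, centre: PointTarget(centre=centre, extent=(2.0, 1.0), label=label),
    )
    fids = _place_surface_fiducials(
        envelope,
        config.n_fiducials,
        config.fiducial_edge_mm,
        config.fiducial_thickness_mm,
        seed,
        config.spacing_mm,
    )
    return SceneSpec(
        name="porcine",
        envelope=envelope,
        fiducials=fids,
        targets=targets,
        needle=NeedleAssembly.default(),
        patient_pose=_patient_pose(config),
        entry_points=entries,
        config=config,
    )


def build_cadaver_scene(config: SceneConfig | None = None, seed: int = 0) -> SceneSpec:
    """Cadaver-like body: two spherical liver lesions + 12 skin tags."""
    config = config or default_config("cadaver")
    envelope = Superellipsoid(config.envelope_semi_axes_mm, config.envelope_exponent)
    lesions = config.lesions or {k: dict(v) for k, v in refdata.CADAVER_LESIONS.items()}
    depths = {label: spec["depth_mm"] for label, spec in lesions.items()}
    diameters = {label: spec["diameter_mm"] for label, spec in lesions.items()}
    targets, entries = _depth_targets(
        envelope,
        depths,
        config.spacing_mm,
        lambda label, centre: SphereLesion(centre=centre, diameter=diameters[label], label=label),
    )
    fids = _place_surface_fiducials(
        envelope,
        config.n_fiducials,
        config.fiducial_edge_mm,
        config.fiducial_thickness_mm,
        seed,
        config.spacing_mm,
    )
    return SceneSpec(
        name="cadaver",
        envelope=envelope,
        fiducials=fids,
        targets=targets,
        needle=NeedleAssembly.default(),
        patient_pose=_patient_pose(config),
        entry_points=entries,
        config=config,
    )


_BUILDERS = {
    "anthro": build_anthropomorphic_scene,
    "porcine": build_porcine_scene,
    "cadaver": build_cadaver_scene,
}


def build_scene(scenario: str, config: SceneConfig | None = None, seed: int = 0) -> SceneSpec:
    try:
        builder = _BUILDERS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}") from None
    return builder(config, seed)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _grid_axes(envelope: Superellipsoid | None, spacing: float, margin: float = 6.0):
    semi = envelope.semi_axes if envelope is not None else (10.0, 10.0, 10.0)
    axes = []
    for half in semi:
        lo = np.floor((-half - margin) / spacing)
        hi = np.ceil((half + margin) / spacing)
        axes.append(np.arange(lo, hi + 1) * spacing)
    return axes


def voxelize(
    scene: SceneSpec,
    spacing: float | None = None,
    intensity_map: dict | None = None,
) -> VoxelVolume:
    """Rasterize a scene into a CT-like volume (voxel-centre-inside test).

    Class precedence at overlapping voxels: fiducial > target > tissue > air;
    among overlapping targets the later-listed target wins (this puts the
    centroid bias from any forced overlap on the larger, earlier bars,
    where it is smallest).
    """
    spacing = float(spacing if spacing is not None else scene.config.spacing_mm)
    if not (0.5 <= spacing <= 3.0):
        raise ValueError("spacing must be within [0.5, 3] mm")
    imap = dict(INTENSITY)
    if intensity_map:
        imap.update(intensity_map)

    xs, ys, zs = _grid_axes(scene.envelope, spacing)
    shape = (len(xs), len(ys), len(zs))
    data = np.full(shape, imap["air"], dtype=np.float32)

    # tissue envelope (an envelope-free scene rasterizes to pure air)
    if scene.envelope is not None:
        a, b, c = scene.envelope.semi_axes
        p = scene.envelope.exponent

        def powp(t: np.ndarray) -> np.ndarray:
            # fast path for the (default) even integer exponent
            if float(p).is_integer() and int(p) % 2 == 0:
                return (t * t) ** (int(p) // 2)
            return np.abs(t) ** p

        u = (
            powp((xs / a).astype(np.float32))[:, None, None]
            + powp((ys / b).astype(np.float32))[None, :, None]
            + powp((zs / c).astype(np.float32))[None, None, :]
        )
        data[u <= 1.0] = imap["tissue"]
        del u

    origin = np.array([xs[0], ys[0], zs[0]])

    def subgrid(lo: np.ndarray, hi: np.ndarray):
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, shape)
        sl = tuple(slice(i0[k], i1[k]) for k in range(3))
        gx, gy, gz = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        return sl, pts

    # targets: rasterize each solid, then resolve overlaps by writing the
    # most-conflicted solid first (later writes win), so that a solid
    # crossed on several sides cedes all its overlap chunks — their
    # centroid effects largely cancel — while its neighbours keep full,
    # symmetric voxel sets.
    rasters = []
    for idx, target in enumerate(scene.targets):
        value = imap["target"] + TARGET_VALUE_STEP * idx
        if isinstance(target, BarTarget):
            pa = np.asarray(target.endpoint_a)
            pb = np.asarray(target.endpoint_b)
            lo = np.minimum(pa, pb) - target.radius
            hi = np.maximum(pa, pb) + target.radius
            sl, pts = subgrid(lo, hi)
            d = pb - pa
            L = np.linalg.norm(d)
            dhat = d / L
            rel = pts - pa
            t = rel @ dhat
            rad2 = np.sum(rel**2, axis=-1) - t**2
            inside = (t >= 0) & (t <= L) & (rad2 <= target.radius**2)
        elif isinstance(target, SphereLesion):
            ctr = np.asarray(target.centre)
            r = target.diameter / 2.0
            sl, pts = subgrid(ctr - r, ctr + r)
            inside = np.sum((pts - ctr) ** 2, axis=-1) <= r**2
        elif isinstance(target, PointTarget):
            ctr = np.asarray(target.centre)
            semi = np.array(
                [target.extent[0] / 2.0, target.extent[1] / 2.0, target.extent[1] / 2.0]
            )
            sl, pts = subgrid(ctr - semi - spacing, ctr + semi + spacing)
            inside = np.sum(((pts - ctr) / semi) ** 2, axis=-1) <= 1.0
            if not np.any(inside):
                # sub-voxel solid: mark the voxel containing the centre
                j = np.round((ctr - origin) / spacing).astype(int)
                inside = np.zeros(tuple(s.stop - s.start for s in sl), dtype=bool)
                inside[tuple(j[k] - sl[k].start for k in range(3))] = True
        else:  # pragma: no cover
            raise TypeError(f"unknown target type {type(target)}")
        rasters.append((idx, value, sl, inside))

    membership = np.zeros(shape, dtype=np.uint8)
    for _, _, sl, inside in rasters:
        membership[sl] += inside
    conflicts = [int(np.sum(membership[sl][inside] >= 2)) for _, _, sl, inside in rasters]
    del membership
    order = sorted(range(len(rasters)), key=lambda k: (-conflicts[k], rasters[k][0]))
    for k in order:
        _, value, sl, inside = rasters[k]
        region = data[sl]
        region[inside] = value
        data[sl] = region
    del rasters

    # fiducials (highest precedence)
    for fid in scene.fiducials:
        frame = fid.frame()
        ctr = np.asarray(fid.centre)
        half = np.array([fid.edge / 2.0, fid.edge / 2.0, fid.thickness / 2.0])
        corners = ctr + (np.array(np.meshgrid(*[[-1, 1]] * 3)).T.reshape(-1, 3) * half) @ frame
        sl, pts = subgrid(corners.min(axis=0), corners.max(axis=0))
        local = (pts - ctr) @ frame.T
        inside = np.all(np.abs(local) <= half, axis=-1)
        region = data[sl]
        region[inside] = imap["fiducial"]
        data[sl] = region

    return VoxelVolume(data, np.full(3, spacing), origin)
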