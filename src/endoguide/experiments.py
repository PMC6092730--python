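"""Scripted accuracy studies and summary statistics.

Three runners mirror the physical accuracy studies (rigid trunk phantom,
breathing porcine model, gated cadaver) plus the pairwise-distance table
statistics.  All standard deviations use the population convention
(divide by n); the choice is recorded in every report.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import refdata
from .camera import default_camera, estimate_pose
from .geometry import FiducialSet, Frame, register_rigid
from .guidance import (
    ControllerConfig,
    NoiseConfig,
    RespirationConfig,
    ScenePlan,
    _observe_points,
    plan_scene,
    simulate_insertion,
)
from .respiration import BreathingMode, RespiratoryModel
from .scene import SceneConfig, SceneSpec, build_scene, default_config

__all__ = [
    "PairwiseDistanceTable",
    "AccuracyReport",
    "reference_table",
    "table1_statistics",
    "run_anthropomorphic",
    "run_porcine",
    "run_cadaver",
]

log = logging.getLogger(__name__)

SD_CONVENTION = "population (divide by n)"


@dataclass
class PairwiseDistanceTable:
    """Real vs pipeline-recovered centre distances, one row per target pair."""

    frame: pd.DataFrame  # columns: pair, real_mm, virtual_mm, abs_diff_mm

    def __post_init__(self) -> None:
        real = self.frame["real_mm"].to_numpy(dtype=float)
        virtual = self.frame["virtual_mm"].to_numpy(dtype=float)
        diff = self.frame["abs_diff_mm"].to_numpy(dtype=float)
        if not np.allclose(diff, np.abs(real - virtual), atol=1e-9):
            raise ValueError("abs_diff_mm must equal |real - virtual|")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairwiseDistanceTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_columns(cls, pairs, real, virtual) -> "PairwiseDistanceTable":
        real = np.asarray(real, dtype=float)
        virtual = np.asarray(virtual, dtype=float)
        return cls(
            pd.DataFrame(
                {
                    "pair": list(pairs),
                    "real_mm": real,
                    "virtual_mm": virtual,
                    "abs_diff_mm": np.abs(real - virtual),
                }
            )
        )


def reference_table() -> PairwiseDistanceTable:
    """The published trunk-phantom distance table."""
    pairs = [f"Bar{i}-Bar{j}" for i, j in refdata.ANTHRO_TABLE]
    real = [row[0] for row in refdata.ANTHRO_TABLE.values()]
    virtual = [row[1] for row in refdata.ANTHRO_TABLE.values()]
    return PairwiseDistanceTable.from_columns(pairs, real, virtual)


def table1_statistics(table: PairwiseDistanceTable) -> tuple[float, float]:
    """Mean and population SD of the absolute-difference column (mm)."""
    diffs = table.frame["abs_diff_mm"].to_numpy(dtype=float)
    if diffs.size == 0:
        raise ValueError("table is empty")
    return float(np.mean(diffs)), float(np.std(diffs))


@dataclass
class AccuracyReport:
    """Per-trial targeting errors with threshold verdict."""

    errors_mm: list[float]
    threshold_mm: float = refdata.ACCURACY_THRESHOLD_MM
    metadata: dict = field(default_factory=dict)

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.errors_mm))

    @property
    def sd_mm(self) -> float:
        return float(np.std(self.errors_mm))

    @property
    def passed(self) -> bool:
        return self.mean_mm < self.threshold_mm

    def to_dict(self) -> dict:
        return {
            "errors_mm": [float(e) for e in self.errors_mm],
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "sd_convention": SD_CONVENTION,
            "threshold_mm": self.threshold_mm,
            "passed": self.passed,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _virtual_centres_one_trial(
    plan: ScenePlan,
    scene: SceneSpec,
    camera_distance: float,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Map planning-scan target centres to world through one tracked registration."""
    T_pat = scene.patient_pose
    truth = scene.fiducial_set()
    skin_top = float(T_pat.apply(truth.points)[:, 2].max())
    camera = default_camera(camera_distance, skin_height_mm=skin_top)
    obs = _observe_points(
        camera,
        T_pat.apply(truth.points),
        list(plan.fiducial_centroids.labels),
        noise.pixel_sigma_px,
        rng,
    )
    est = estimate_pose(obs, plan.fiducial_centroids, camera)
    tracked = est.pose.apply(plan.fiducial_centroids.points)
    if noise.fiducial_sigma_mm > 0:
        tracked = tracked + rng.normal(0.0, noise.fiducial_sigma_mm, size=tracked.shape)
    reg = register_rigid(
        plan.fiducial_centroids,
        FiducialSet(tracked, list(plan.fiducial_centroids.labels), Frame.TRACKER),
    )
    return {
        label: reg.transform.apply(centre)
        for label, centre in plan.target_centres.items()
    }


def run_anthropomorphic(
    config: SceneConfig | None = None,
    n_trials: int = 10,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    camera_distances: tuple[float, ...] = (300.0, 400.0, 500.0),
    plan: ScenePlan | None = None,
) -> tuple[PairwiseDistanceTable, AccuracyReport]:
    """Trunk-phantom study: real vs pipeline-recovered pairwise bar distances.

    Real distances are the ground-truth centre distances of the generated
    scene; virtual distances map the segmented centres through the full
    observe/pose/register chain, averaged over trials and camera distances.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or default_config("anthro")
    noise = noise or NoiseConfig()
    scene = build_scene("anthro", config, seed=config.seed)
    plan = plan or plan_scene(scene)
    labels = scene.target_labels
    pairs = list(itertools.combinations(range(len(labels)), 2))

    rng = np.random.default_rng(seed)
    virtual_sums = np.zeros(len(pairs))
    count = 0
    dropped = 0
    for trial in range(n_trials):
        for dist in camera_distances:
            try:
                centres = _virtual_centres_one_trial(plan, scene, dist, noise, rng)
            except Exception as exc:  # pipeline failure drops the trial
                dropped += 1
                log.warning("trial %d @ %.0f mm dropped: %s", trial, dist, exc)
                continue
            pts = np.array([centres[labels[k]] for k in range(len(labels))])
            virtual_sums += [np.linalg.norm(pts[i] - pts[j]) for i, j in pairs]
            count += 1
    if count == 0:
        raise RuntimeError("all trials failed")
    virtual = virtual_sums / count

    true_pts = np.array([scene.target_centre(l) for l in labels])
    real = [float(np.linalg.norm(true_pts[i] - true_pts[j])) for i, j in pairs]
    table = PairwiseDistanceTable.from_columns(
        [f"{labels[i]}-{labels[j]}" for i, j in pairs], real, virtual
    )
    mean, sd = table1_statistics(table)
    report = AccuracyReport(
        errors_mm=table.frame["abs_diff_mm"].tolist(),
        metadata={
            "scenario": "anthro",
            "n_trials": n_trials,
            "camera_distances_mm": list(camera_distances),
            "dropped_trials": dropped,
            "mean_abs_diff_mm": mean,
            "sd_abs_diff_mm": sd,
        },
    )
    return table, report


def _run_insertions(
    scene: SceneSpec,
    targets: list[str],
    n_reps: int,
    seed: int,
    noise: NoiseConfig,
    respiration: RespirationConfig | None,
    controller: ControllerConfig | None,
    plan: ScenePlan,
) -> tuple[list[float], dict[str, list[float]], int]:
    errors: list[float] = []
    per_target: dict[str, list[float]] = {t: [] for t in targets}
    dropped = 0
    for rep in range(n_reps):
        for k, target in enumerate(targets):
            try:
                result = simulate_insertion(
                    scene,
                    noise=noise,
                    respiration=respiration,
                    controller=controller,
                    seed=seed + rep,
                    target=target,
                    plan=plan,
                )
            except RuntimeError as exc:
                dropped += 1
                log.warning("rep %d target %s dropped: %s", rep, target, exc)
                continue
            errors.append(result.final_true_error_mm)
            per_target[target].append(result.final_true_error_mm)
    if not errors:
        raise RuntimeError("all insertions failed")
    return errors, per_target, dropped


def run_porcine(
    config: SceneConfig | None = None,
    gated: bool = True,
    n_reps: int = 100,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    respiratory_model: RespiratoryModel | None = None,
    controller: ControllerConfig | None = None,
    plan: ScenePlan | None = None,
) -> AccuracyReport:
    """Breathing study: guided insertions into all three implanted targets."""
    config = config or default_config("porcine")
    noise = noise or NoiseConfig()
    model = respiratory_model or RespiratoryModel()
    scene = build_scene("porcine", config, seed=config.seed)
    plan = plan or plan_scene(scene)
    respiration = RespirationConfig(
        model=model, mode=BreathingMode.GATED if gated else BreathingMode.FREE
    )
    errors, per_target, dropped = _run_insertions(
        scene, scene.target_labels, n_reps, seed, noise, respiration, controller, plan
    )
    return AccuracyReport(
        errors_mm=errors,
        metadata={
            "scenario": "porcine",
            "gated": gated,
            "n_reps": n_reps,
            "dropped": dropped,
            "per_target_mean_mm": {t: float(np.mean(v)) for t, v in per_target.items() if v},
            "target_depths_mm": dict(config.target_depths_mm),
        },
    )


def run_cadaver(
    config: SceneConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    controller: ControllerConfig | None = None,
    plan: ScenePlan | None = None,
) -> AccuracyReport:
    """Gated insertions into both spherical lesions, per-lesion reporting."""
    config = config or default_config("cadaver")
    noise = noise or NoiseConfig()
    scene = build_scene("cadaver", config, seed=config.seed)
    plan = plan or plan_scene(scene)
    errors, per_target, dropped = _run_insertions(
        scene, scene.target_labels, n_reps, seed, noise, None, controller, plan
    )
    lesions = {}
    for t in scene.targets:
        lesions[t.label] = {
            "diameter_mm": t.diameter,
            "mean_error_mm": float(np.mean(per_target[t.label])) if per_target[t.label] else None,
            "n": len(per_target[t.label]),
        }
    return AccuracyReport(
        errors_mm=errors,
        metadata={
            "scenario": "cadaver",
            "gated": True,
            "n_reps": n_reps,
            "dropped": dropped,
            "lesions": lesions,
        },
    )
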