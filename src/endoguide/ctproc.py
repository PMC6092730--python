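"""Segmentation of a voxel volume and marker coordinate extraction.

Threshold segmentation into 26-connected components plus per-component
principal-component frames (centroid, orthonormal axes, eigenvalues) — the
pre-treatment image-processing stage feeding the registration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene import VoxelVolume

__all__ = [
    "ComponentClass",
    "LabelMap",
    "MarkerFrame",
    "segment",
    "extract_marker_frame",
    "target_centre",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


class ComponentClass(str, Enum):
    FIDUCIAL = "FIDUCIAL"
    TARGET = "TARGET"
    TISSUE = "TISSUE"


@dataclass
class LabelMap:
    """Connected-component labels aligned with a source volume.

    Label 0 is background; labels 1..n are contiguous, ordered by
    descending component size (ties broken by the lexicographically
    smallest member voxel index).
    """

    grid: np.ndarray
    n_components: int
    component_class: ComponentClass | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)

    def sizes(self) -> np.ndarray:
        """Voxel count per label (index 0 -> label 1)."""
        flat = self.grid.ravel()
        nz = np.flatnonzero(flat)
        return np.bincount(flat[nz], minlength=self.n_components + 1)[1:]

    def to_volume(self, volume: VoxelVolume) -> VoxelVolume:
        """Package the integer grid with the source volume's geometry."""
        if self.grid.shape != volume.shape:
            raise ValueError("label map and volume shapes differ")
        return VoxelVolume(self.grid.astype(np.int16), volume.spacing, volume.origin)


def segment(
    volume: VoxelVolume,
    threshold_low: float,
    threshold_high: float,
    min_size: int = 4,
    component_class: ComponentClass | None = None,
) -> LabelMap:
    """Group voxels with intensity in [low, high] into 26-connected components.

    Components smaller than *min_size* voxels are discarded.  An empty
    intensity band yields an empty label map, not an error.
    """
    if not threshold_low < threshold_high:
        raise ValueError("threshold_low must be < threshold_high")
    mask = (volume.data >= threshold_low) & (volume.data <= threshold_high)
    raw, n_raw = ndimage.label(mask, structure=_STRUCTURE_26)
    if n_raw == 0:
        return LabelMap(np.zeros(volume.shape, dtype=np.int32), 0, component_class)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    sizes = np.bincount(flat[nz], minlength=n_raw + 1)[1:]
    # tie-break: smallest flat voxel index of each component
    first_index = np.full(n_raw + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first_index, flat[nz], nz)
    order = sorted(
        (lab for lab in range(1, n_raw + 1) if sizes[lab - 1] >= min_size),
        key=lambda lab: (-int(sizes[lab - 1]), int(first_index[lab])),
    )
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    for new, lab in enumerate(order, start=1):
        remap[lab] = new
    return LabelMap(remap[raw], len(order), component_class)


@dataclass
class MarkerFrame:
    """Centroid + principal axes (rows, descending variance) of a component."""

    centroid: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray

    @property
    def normal(self) -> np.ndarray:
        """Smallest-variance axis — the surface normal for thin flat tags."""
        return self.axes[2]


def _component_coords(labelmap: LabelMap, label: int, volume: VoxelVolume) -> np.ndarray:
    if labelmap.grid.shape != volume.shape:
        raise ValueError("label map and volume shapes differ")
    if not (1 <= label <= labelmap.n_components):
        raise KeyError(f"label {label} not present (1..{labelmap.n_components})")
    objects = ndimage.find_objects(labelmap.grid, max_label=label)
    sl = objects[label - 1]
    if sl is None:
        raise KeyError(f"label {label} not present")
    idx = np.argwhere(labelmap.grid[sl] == label) + [s.start for s in sl]
    return volume.index_to_world(idx)


def extract_marker_frame(
    labelmap: LabelMap,
    label: int,
    volume: VoxelVolume,
    reference_point: np.ndarray | None = None,
) -> MarkerFrame:
    """PCA frame of one labelled component.

    The centroid is the unweighted mean of member-voxel world coordinates;
    axes and eigenvalues come from the eigendecomposition of their 3x3
    covariance (population convention).  Sign fixing: the smallest-variance
    axis points away from *reference_point* (default: the volume's world
    centre, a proxy for the body centroid); the first axis has positive dot
    product with world +x (falling back to +y when orthogonal); the second
    axis completes a right-handed frame.
    """
    coords = _component_coords(labelmap, label, volume)
    if len(coords) < 4:
        raise ValueError(f"label {label} has {len(coords)} voxels; >= 4 required")
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T, bias=True)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    eigenvalues = np.clip(w[order], 0.0, None)
    axes = v[:, order].T  # rows

    ref = (
        volume.world_centre() if reference_point is None else np.asarray(reference_point, float)
    )
    if axes[2] @ (centroid - ref) < 0:
        axes[2] = -axes[2]
    first = axes[0] @ np.array([1.0, 0.0, 0.0])
    if abs(first) < 1e-9:
        first = axes[0] @ np.array([0.0, 1.0, 0.0])
    if first < 0:
        axes[0] = -axes[0]
    axes[1] = np.cross(axes[2], axes[0])
    return MarkerFrame(centroid=centroid, axes=axes, eigenvalues=eigenvalues)


def target_centre(labelmap: LabelMap, label: int, volume: VoxelVolume) -> np.ndarray:
    """Unweighted centroid (mm, world) of a labelled component."""
    return _component_coords(labelmap, label, volume).mean(axis=0)


def marker_frame_table(
    labelmap: LabelMap, volume: VoxelVolume, path: str | Path | None = None
) -> pd.DataFrame:
    """CSV-ready table of all marker frames in a label map."""
    rows = []
    for label in range(1, labelmap.n_components + 1):
        mf = extract_marker_frame(labelmap, label, volume)
        row = {"label": label}
        for axis, name in zip("xyz", range(3)):
            row[f"centroid_{axis}_mm"] = mf.centroid[name]
        for k in range(3):
            for axis, name in zip("xyz", range(3)):
                row[f"axis{k + 1}_{axis}"] = mf.axes[k, name]
            row[f"eigenvalue{k + 1}_mm2"] = mf.eigenvalues[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
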