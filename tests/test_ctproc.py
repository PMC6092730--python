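from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoguide.ctproc import (
    LabelMap,
    extract_marker_frame,
    segment,
    target_centre,
)
from endoguide.scene import (
    FIDUCIAL_BAND,
    INTENSITY,
    SquareFiducial,
    voxelize,
)
from test_scene import _bare_scene


def _volume_from_mask(mask, value=3000.0, spacing=1.0):
    from endoguide.scene import VoxelVolume

    data = np.full(mask.shape, -1000.0, dtype=np.float32)
    data[mask] = value
    return VoxelVolume(data, [spacing] * 3, [0.0, 0.0, 0.0])


def _flood_fill_count(mask, min_size=1):
    """Brute-force 26-connected component count (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    shape = mask.shape
    neighbours = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in neighbours:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[k] < shape[k] for k in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        queue.append(n)
        if size >= min_size:
            count += 1
    return count


class TestSegment:
    def test_all_air_no_components(self):
        vol = voxelize(_bare_scene(), spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        assert lm.n_components == 0

    def test_two_separated_cubes(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[1:3, 1:3, 4:6] = True  # one background voxel between
        lm = segment(_volume_from_mask(mask), 2000, 4000)
        assert lm.n_components == 2

    def test_touching_cubes_merge(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[1:3, 1:3, 3:5] = True  # face-to-face
        lm = segment(_volume_from_mask(mask), 2000, 4000)
        assert lm.n_components == 1

    def test_corner_connected_is_one_component(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2, 2, 2] = True  # touches only at a corner: 26-connected
        mask[2:4, 2:4, 2:4] = True
        lm = segment(_volume_from_mask(mask), 2000, 4000, min_size=1)
        assert lm.n_components == 1

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), p=st.floats(0.05, 0.4))
    def test_flood_fill_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < p
        lm = segment(_volume_from_mask(mask), 2000, 4000, min_size=1)
        assert lm.n_components == _flood_fill_count(mask)

    def test_min_size_filter(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:4, 1:4, 1:4] = True  # 27 voxels
        mask[7, 7, 7] = True  # speck
        lm = segment(_volume_from_mask(mask), 2000, 4000, min_size=4)
        assert lm.n_components == 1

    def test_labels_ordered_by_size(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:3, 1:3, 1:3] = True  # 8 voxels
        mask[6:10, 6:10, 6:10] = True  # 64 voxels
        vol = _volume_from_mask(mask)
        lm = segment(vol, 2000, 4000)
        sizes = lm.sizes()
        assert sizes[0] == 64 and sizes[1] == 8

    def test_thresholds_validated(self):
        vol = voxelize(_bare_scene(), spacing=1.0)
        with pytest.raises(ValueError):
            segment(vol, 100.0, 100.0)

    def test_idempotent_component_count(self, porcine_scene):
        vol = voxelize(porcine_scene, 2.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        revox = _volume_from_mask(lm.grid > 0)
        lm2 = segment(revox, 2000, 4000)
        assert lm2.n_components == lm.n_components

    def test_anthro_30_fiducials_coarse(self, anthro_scene):
        vol = voxelize(anthro_scene, 2.0)
        assert segment(vol, *FIDUCIAL_BAND).n_components == 30


def _slab_scene(centre=(10.0, 20.0, 30.0), normal=(0.0, 0.0, 1.0), u=(1.0, 0.0, 0.0)):
    fid = SquareFiducial(
        centre=centre, normal=normal, in_plane_axis=u, edge=35.0, thickness=2.0, label="f"
    )
    return _bare_scene(fiducials=[fid], semi_axes=(80.0, 80.0, 80.0))


class TestMarkerFrame:
    def test_slab_centroid(self):
        scene = _slab_scene()
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        mf = extract_marker_frame(lm, 1, vol, reference_point=[10.0, 20.0, -50.0])
        assert np.all(np.abs(mf.centroid - [10, 20, 30]) <= 0.5)

    def test_slab_normal_axis_aligned(self):
        scene = _slab_scene()
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        mf = extract_marker_frame(lm, 1, vol, reference_point=[10.0, 20.0, -50.0])
        angle = np.degrees(np.arccos(np.clip(abs(mf.normal[2]), 0, 1)))
        assert angle < 2.0
        assert mf.normal[2] > 0  # away from the reference point

    @pytest.mark.parametrize("theta_deg", [45.0, 30.0])
    def test_slab_normal_rotated(self, theta_deg):
        th = np.radians(theta_deg)
        normal = (0.0, -np.sin(th), np.cos(th))
        scene = _slab_scene(normal=normal, u=(1.0, 0.0, 0.0))
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        mf = extract_marker_frame(lm, 1, vol, reference_point=[10.0, 20.0, -50.0])
        cosang = np.clip(abs(mf.normal @ normal), 0, 1)
        assert np.degrees(np.arccos(cosang)) < 2.0

    def test_axes_orthonormal_right_handed(self):
        scene = _slab_scene(normal=(0.0, -np.sin(0.5), np.cos(0.5)))
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        mf = extract_marker_frame(lm, 1, vol)
        assert np.allclose(mf.axes @ mf.axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(mf.axes) > 0.999999999
        assert mf.eigenvalues[0] >= mf.eigenvalues[1] >= mf.eigenvalues[2] >= 0

    def test_equivariance_under_rotation(self):
        # rotating the scene rotates the recovered frame (within tolerance)
        th = np.radians(30.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        base_normal = np.array([0.0, -np.sin(0.4), np.cos(0.4)])
        base_centre = np.array([10.0, 20.0, 30.0])
        u0 = np.array([1.0, 0.0, 0.0])
        u0 = u0 - (u0 @ base_normal) * base_normal
        u0 /= np.linalg.norm(u0)
        frames = []
        for rot in (np.eye(3), R):
            scene = _slab_scene(
                centre=tuple(rot @ base_centre),
                normal=tuple(rot @ base_normal),
                u=tuple(rot @ u0),
            )
            vol = voxelize(scene, spacing=1.0)
            lm = segment(vol, *FIDUCIAL_BAND)
            frames.append(extract_marker_frame(lm, 1, vol, reference_point=[0, 0, -80.0]))
        centroid_rotated = R @ frames[0].centroid
        assert np.linalg.norm(centroid_rotated - frames[1].centroid) < np.sqrt(3.0)
        cosang = np.clip(abs((R @ frames[0].normal) @ frames[1].normal), 0, 1)
        assert np.degrees(np.arccos(cosang)) < 3.0

    def test_missing_label_raises(self):
        scene = _slab_scene()
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        with pytest.raises(KeyError):
            extract_marker_frame(lm, 5, vol)

    def test_small_component_raises(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2, 2, 2:4] = True
        vol = _volume_from_mask(mask)
        lm = segment(vol, 2000, 4000, min_size=1)
        with pytest.raises(ValueError):
            extract_marker_frame(lm, 1, vol)


class TestTargetCentre:
    def test_single_voxel_exact(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2, 3, 4] = True
        vol = _volume_from_mask(mask, spacing=2.0)
        lm = segment(vol, 2000, 4000, min_size=1)
        assert np.allclose(target_centre(lm, 1, vol), [4.0, 6.0, 8.0])

    def test_sphere_centroid(self):
        from endoguide.scene import SphereLesion

        sphere = SphereLesion(centre=(3.0, -2.0, 5.0), diameter=10.0, label="s")
        scene = _bare_scene(targets=[sphere], semi_axes=(30.0,) * 3)
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, 250, 1500, min_size=1)
        c = target_centre(lm, 1, vol)
        assert np.linalg.norm(c - [3, -2, 5]) < np.sqrt(3.0)

    def test_bar_centroid_at_axis_midpoint(self):
        from endoguide.scene import BarTarget

        bar = BarTarget(
            endpoint_a=(-40.0, 0.0, 0.0), endpoint_b=(40.0, 0.0, 0.0), radius=8.0, label="b"
        )
        scene = _bare_scene(targets=[bar], semi_axes=(60.0,) * 3)
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, 250, 1500, min_size=1)
        assert np.linalg.norm(target_centre(lm, 1, vol)) < np.sqrt(3.0)

    def test_missing_label(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        vol = _volume_from_mask(mask)
        lm = segment(vol, 2000, 4000, min_size=1)
        with pytest.raises(KeyError):
            target_centre(lm, 2, vol)


class TestFiducialRecovery:
    @pytest.mark.parametrize(
        "fixture", ["porcine_plan", "cadaver_plan", "anthro_plan"]
    )
    def test_recovery_rms(self, fixture, request):
        plan = request.getfixturevalue(fixture)
        truth = plan.scene.fiducial_set()
        assert len(plan.fiducial_centroids) == len(truth)
        err = np.linalg.norm(plan.fiducial_centroids.points - truth.points, axis=1)
        assert np.sqrt(np.mean(err**2)) < 0.6


class TestExports:
    def test_labelmap_to_volume(self, tmp_path):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        vol = _volume_from_mask(mask)
        lm = segment(vol, 2000, 4000)
        out = lm.to_volume(vol)
        assert out.data.dtype == np.int16
        assert out.shape == vol.shape
        path = tmp_path / "labels.nii"
        out.to_nifti(path)
        from endoguide.scene import VoxelVolume

        back = VoxelVolume.from_nifti(path)
        assert np.array_equal(np.asarray(back.data), np.asarray(out.data))

    def test_marker_frame_table(self, tmp_path):
        from endoguide.ctproc import marker_frame_table

        scene = _slab_scene()
        vol = voxelize(scene, spacing=1.0)
        lm = segment(vol, *FIDUCIAL_BAND)
        df = marker_frame_table(lm, vol, tmp_path / "frames.csv")
        assert len(df) == 1
        assert (tmp_path / "frames.csv").exists()
        assert {"label", "centroid_x_mm", "axis3_z", "eigenvalue1_mm2"} <= set(df.columns)
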