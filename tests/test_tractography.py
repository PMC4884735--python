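"""Streamline tracker: interpolation, termination rules, length filtering."""

import numpy as np
import pytest

from ficdmap import Bundle, PhantomSpec, TensorVolume, TrackingParams, make_tensor_phantom
from ficdmap.core import fa_from_eigenvalues, matrices_to_tensors
from ficdmap.phantoms import arc_centerline, axially_symmetric_tensor
from ficdmap.tractography import check_streamline, sample_field, track_from_mask, track_streamline


def uniform_volume(shape=(40, 40, 40), direction=(1.0, 0.0, 0.0), fa=0.8) -> TensorVolume:
    """A uniform axially symmetric tensor field centered on the origin."""
    tensor = matrices_to_tensors(axially_symmetric_tensor(direction, fa))
    affine = np.eye(4)
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0
    return TensorVolume(np.tile(tensor, shape + (1,)), affine)


class TestSampleField:
    def test_uniform_field_constant_everywhere(self):
        vol = uniform_volume()
        fa1, d1 = sample_field(vol, [0.3, -4.7, 2.2])
        fa2, d2 = sample_field(vol, [11.0, 3.0, -9.5])
        assert fa1 == pytest.approx(0.8, abs=1e-12)
        assert fa1 == pytest.approx(fa2, abs=1e-12)
        assert abs(float(d1 @ d2)) == pytest.approx(1.0, abs=1e-12)

    def test_voxel_center_is_exact(self, straight_bundle_volume):
        _, vol = straight_bundle_volume
        ijk = (30, 30, 30)
        fa, _ = sample_field(vol, vol.voxel_to_world(ijk))
        assert fa == pytest.approx(float(vol.fa[ijk]), abs=1e-12)

    def test_midpoint_fa_is_fa_of_mean_tensor(self):
        # two diagonal tensors sharing eigenvectors; the midpoint tensor is
        # their average, whose FA has a closed form from its eigenvalues
        low = np.diag([2.0, 1.0, 1.0]) * 1e-4
        high = np.diag([9.0, 1.0, 1.0]) * 1e-4
        tensors = np.zeros((2, 1, 1, 6))
        tensors[0, 0, 0] = matrices_to_tensors(low)
        tensors[1, 0, 0] = matrices_to_tensors(high)
        # make the grid 3D-interpolable by padding y/z
        grid = np.tile(tensors, (1, 2, 2, 1))
        vol = TensorVolume(grid, np.eye(4))
        fa_mid, _ = sample_field(vol, [0.5, 0.5, 0.5])
        expected = fa_from_eigenvalues(np.linalg.eigvalsh((low + high) / 2.0))
        assert fa_mid == pytest.approx(float(expected), abs=1e-12)

    def test_out_of_bounds_sentinel(self):
        vol = uniform_volume((8, 8, 8))
        fa, d = sample_field(vol, [100.0, 0.0, 0.0])
        assert np.isnan(fa) and d is None


class TestTrackStreamline:
    def test_straight_track_spans_the_box(self):
        vol = uniform_volume((60, 60, 60))
        params = TrackingParams()
        s = track_streamline(vol, np.zeros(3), params)
        extent = 59.0  # between boundary voxel centers
        assert abs(s.length - extent) <= 2 * params.step_mm
        # straight: perpendicular deviation below solver tolerance
        assert np.abs(s.points[:, 1:]).max() < 1e-9
        assert s.mean_fa == pytest.approx(0.8, abs=1e-9)
        assert check_streamline(s, vol, params)

    def test_seed_below_fa_threshold_returns_none(self):
        vol = uniform_volume(fa=0.10)
        assert track_streamline(vol, np.zeros(3), TrackingParams()) is None

    def test_track_terminates_at_90_degree_flip(self):
        shape = (40, 40, 40)
        x_t = matrices_to_tensors(axially_symmetric_tensor([1, 0, 0], 0.8))
        y_t = matrices_to_tensors(axially_symmetric_tensor([0, 1, 0], 0.8))
        grid = np.tile(x_t, shape + (1,))
        grid[30:] = y_t  # flip plane at voxel x = 30 (world x = 10.5)
        affine = np.eye(4)
        affine[:3, 3] = -(np.array(shape) - 1) / 2.0
        vol = TensorVolume(grid, affine)
        s = track_streamline(vol, np.zeros(3), TrackingParams())
        assert s.points[:, 0].max() < 11.0  # stopped at the flip plane
        assert s.points[:, 0].min() < -19.0  # the other branch ran to the edge

    def test_step_halving_keeps_length(self):
        vol = uniform_volume((50, 50, 50))
        a = track_streamline(vol, np.zeros(3), TrackingParams(step_mm=0.5))
        b = track_streamline(vol, np.zeros(3), TrackingParams(step_mm=0.25))
        assert abs(a.length - b.length) <= 0.5 + 1e-9

    def test_curved_arc_tracked_within_two_steps(self):
        arc = arc_centerline(20.0, 90.0, center=(0.0, -20.0, 0.0), n=181)
        spec = PhantomSpec(
            grid_shape=(64, 64, 16), bundles=[Bundle(arc, radius=3.0, fa=0.8)], mesh_radius=5.0
        )
        vol = make_tensor_phantom(spec)
        params = TrackingParams(min_len_mm=10.0)
        s = track_streamline(vol, arc[90], params)
        assert s is not None and s.length > 15.0
        # distance from every tracked point to the analytic circle
        center = np.array([0.0, -20.0, 0.0])
        radial = np.linalg.norm((s.points - center)[:, :2], axis=1)
        assert np.abs(radial - 20.0).max() <= 2 * params.step_mm


class TestTrackFromMask:
    def test_every_seed_in_bundle_survives(self, straight_bundle_volume):
        spec, vol = straight_bundle_volume
        centers = vol.voxel_centers()
        inside = np.linalg.norm(centers[..., 1:], axis=-1) <= 2.0
        mask = np.argwhere(inside)[:100]
        tracks = track_from_mask(vol, mask, TrackingParams())
        assert len(tracks) == 100
        assert np.all(tracks.lengths >= 30.0) and np.all(tracks.lengths <= 300.0)
        assert np.allclose(tracks.mean_fas, 0.8, atol=1e-6)

    def test_short_bundle_filtered_out(self):
        # 20 mm bundle in a low-FA background: all tracks below the minimum
        spec = PhantomSpec(
            grid_shape=(60, 60, 60),
            bundles=[Bundle(np.array([[-10.0, 0, 0], [10.0, 0, 0]]), radius=3.0, fa=0.8)],
            fa_background=0.05,
            mesh_radius=20.0,
        )
        vol = make_tensor_phantom(spec)
        mask = np.argwhere(np.linalg.norm(vol.voxel_centers(), axis=-1) <= 2.0)
        tracks = track_from_mask(vol, mask, TrackingParams())
        assert len(tracks) == 0

    def test_exact_minimum_length_retained(self):
        # 0.5 mm voxels, 61 centers -> extent exactly 30.0 mm along x
        shape = (61, 9, 9)
        tensor = matrices_to_tensors(axially_symmetric_tensor([1, 0, 0], 0.8))
        affine = np.diag([0.5, 0.5, 0.5, 1.0])
        affine[:3, 3] = [0.0, -2.0, -2.0]
        vol = TensorVolume(np.tile(tensor, shape + (1,)), affine)
        tracks = track_from_mask(vol, np.array([[30, 4, 4]]), TrackingParams())
        assert len(tracks) == 1
        assert tracks.streamlines[0].length == pytest.approx(30.0, abs=1e-9)

    def test_empty_mask_empty_tractogram(self, straight_bundle_volume):
        _, vol = straight_bundle_volume
        assert len(track_from_mask(vol, np.empty((0, 3)), TrackingParams())) == 0

    def test_emitted_streamlines_satisfy_invariants(self, straight_bundle_volume):
        _, vol = straight_bundle_volume
        params = TrackingParams()
        mask = np.argwhere(np.linalg.norm(vol.voxel_centers()[..., 1:], axis=-1) <= 1.0)[:20]
        tracks = track_from_mask(vol, mask, params)
        assert all(check_streamline(s, vol, params) for s in tracks)


class TestParams:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(fa_threshold=1.5),
            dict(turning_angle_deg=0.0),
            dict(step_mm=-1.0),
            dict(smoothing=1.0),
            dict(min_len_mm=50.0, max_len_mm=40.0),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            TrackingParams(**bad)
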