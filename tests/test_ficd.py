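"""FiCD statistic, vertex projection, smoothing and the Z-transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ficdmap import (
    Bundle,
    PhantomSpec,
    Streamline,
    TrackingParams,
    Tractogram,
    compute_ficd,
    ficd_per_cu,
    make_cortex_mesh,
    make_tensor_phantom,
    parcellate_surface,
    project_to_vertices,
    smooth_surface_map,
    z_transform_hemisphere,
)
from ficdmap.parcellation import CorticalUnit
from ficdmap.smoothing import estimate_fwhm

from conftest import sphere_mesh


def toy_tractogram(mean_fas) -> Tractogram:
    pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    return Tractogram([Streamline(pts, mean_fa=fa) for fa in mean_fas])


def toy_cu(seed_volume: float) -> CorticalUnit:
    cu = CorticalUnit(0, np.arange(3), np.arange(1), 1.0)
    cu.seed_voxels = np.zeros((max(int(seed_volume), 1), 3), dtype=int)
    cu.seed_volume = seed_volume
    return cu


class TestComputeFicd:
    def test_printed_formula(self):
        assert compute_ficd(toy_cu(2.0), toy_tractogram([0.5, 0.4, 0.3])) == pytest.approx(0.6, abs=1e-12)

    def test_no_fibers_gives_zero(self):
        assert compute_ficd(toy_cu(2.0), toy_tractogram([])) == 0.0

    def test_single_fiber(self):
        assert compute_ficd(toy_cu(1.0), toy_tractogram([0.8])) == pytest.approx(0.8, abs=1e-12)

    def test_zero_seed_volume_undefined(self):
        with pytest.raises(ValueError, match="seed volume"):
            compute_ficd(toy_cu(0.0), toy_tractogram([0.5]))

    def test_scales_inversely_with_seed_volume(self):
        tracks = toy_tractogram([0.5, 0.3])
        assert compute_ficd(toy_cu(2.0), tracks) == pytest.approx(
            compute_ficd(toy_cu(4.0), tracks) * 2.0, abs=1e-12
        )

    def test_per_point_alternative(self):
        # 3-point fiber, constant FA 0.6: per-point sum = 3 * 0.6
        s = Streamline(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]), mean_fa=0.6)
        t = Tractogram([s])
        assert compute_ficd(toy_cu(1.0), t, per_point=True) == pytest.approx(1.8, abs=1e-12)


class TestProjection:
    @pytest.fixture(scope="class")
    def parc(self):
        return parcellate_surface(sphere_mesh(2, 10.0), 6, rng_seed=0)

    def test_piecewise_constant_two_values(self, parc):
        values = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        vmap = project_to_vertices(parc, values)
        assert set(np.unique(vmap)) == {1.0, 2.0}

    def test_constant_case(self, parc):
        vmap = project_to_vertices(parc, np.full(6, 3.25))
        assert np.all(vmap == 3.25)

    def test_area_weighted_mean_matches_direct_sum(self, parc):
        values = np.arange(6, dtype=float) + 1.0
        vmap = project_to_vertices(parc, values)
        mesh = parc.mesh
        lhs = float(mesh.vertex_areas @ vmap)
        owner_area = np.bincount(parc.vertex_labels, weights=mesh.vertex_areas, minlength=6)
        assert lhs == pytest.approx(float(owner_area @ values), rel=1e-12)

    def test_nan_propagates_for_missing_cu(self, parc):
        values = np.array([1.0, np.nan, 1.0, 1.0, 1.0, 1.0])
        vmap = project_to_vertices(parc, values)
        assert np.isnan(vmap).any() and np.isfinite(vmap).any()


class TestSmoothing:
    @pytest.fixture(scope="class")
    def mesh(self):
        return sphere_mesh(3, 50.0)

    def test_constant_map_is_fixed_point(self, mesh):
        out = smooth_surface_map(mesh, np.full(mesh.n_vertices, 2.5), 10.0)
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_zero_fwhm_is_identity(self, mesh):
        rng = np.random.default_rng(0)
        x = rng.normal(size=mesh.n_vertices)
        assert np.array_equal(smooth_surface_map(mesh, x, 0.0), x)

    def test_delta_integral_preserved(self, mesh):
        delta = np.zeros(mesh.n_vertices)
        delta[17] = 1.0
        before = float(mesh.vertex_areas @ delta)
        after = float(mesh.vertex_areas @ smooth_surface_map(mesh, delta, 15.0))
        assert abs(after - before) / before < 0.01

    def test_white_noise_reaches_requested_fwhm(self):
        mesh = sphere_mesh(4, 100.0)  # 6 mm edges: dense relative to 15 mm
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((12, mesh.n_vertices))
        smoothed = np.vstack([smooth_surface_map(mesh, n, 15.0) for n in noise])
        assert estimate_fwhm(mesh, smoothed) == pytest.approx(15.0, abs=2.0)

    def test_unsmoothed_noise_estimates_below_vertex_scale(self):
        mesh = sphere_mesh(4, 50.0)
        rng = np.random.default_rng(2)
        est = estimate_fwhm(mesh, rng.standard_normal((12, mesh.n_vertices)))
        assert est < 3.0

    def test_estimate_invariant_to_scaling(self, mesh):
        rng = np.random.default_rng(3)
        maps = smooth_surface_map(mesh, rng.standard_normal(mesh.n_vertices), 20.0)[None]
        assert estimate_fwhm(mesh, maps) == pytest.approx(estimate_fwhm(mesh, 7.0 * maps), rel=1e-12)

    def test_negative_fwhm_rejected(self, mesh):
        with pytest.raises(ValueError):
            smooth_surface_map(mesh, np.zeros(mesh.n_vertices), -1.0)


class TestZTransform:
    def test_three_point_map(self):
        assert np.allclose(z_transform_hemisphere(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        z = z_transform_hemisphere(rng.normal(3.0, 2.0, size=500))
        assert abs(z.mean()) < 1e-9
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_invariant_to_affine_rescaling(self, a, b):
        x = np.array([0.3, -1.2, 4.5, 2.2, -0.7])
        assert np.allclose(z_transform_hemisphere(a * x + b), z_transform_hemisphere(x), atol=1e-8)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            z_transform_hemisphere(np.full(10, 3.0))

    def test_nan_vertices_ignored_and_propagated(self):
        x = np.array([1.0, 2.0, 3.0, np.nan])
        z = z_transform_hemisphere(x)
        assert np.isnan(z[3]) and np.allclose(z[:3], [-1, 0, 1])


class TestEndToEnd:
    def test_bundle_footprint_has_higher_ficd(self):
        """On a straight-bundle phantom, CUs whose seed layer touches the
        bundle must out-score background CUs (one-sided check)."""
        spec = PhantomSpec(
            grid_shape=(50, 50, 50),
            bundles=[Bundle(np.array([[-24.5, 0, 0], [24.5, 0, 0]]), radius=4.0, fa=0.8)],
            mesh_radius=15.0,
            mesh_subdivisions=3,
        )
        vol = make_tensor_phantom(spec)
        mesh = make_cortex_mesh(spec)
        parc = parcellate_surface(mesh, 48, rng_seed=0)
        values, _ = ficd_per_cu(parc, vol, TrackingParams())
        assert np.all(np.isfinite(values))
        # bundle pierces the sphere near (+-15, 0, 0)
        footprint, background = [], []
        for cu in parc:
            c = mesh.vertices[cu.vertex_ids].mean(axis=0)
            axis_dist = np.linalg.norm(c[1:])
            if axis_dist <= spec.bundles[0].radius:
                footprint.append(values[cu.id])
            elif axis_dist > 3 * spec.bundles[0].radius:
                background.append(values[cu.id])
        assert footprint and background
        assert min(footprint) > max(background)
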