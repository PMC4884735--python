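"""Cluster ROI metrics, group tests and partial correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ficdmap import (
    Bundle,
    CohortSpec,
    PhantomSpec,
    TrackingParams,
    contiguous_patch,
    extract_cluster_metrics,
    make_cohort,
    make_cortex_mesh,
    make_tensor_phantom,
    mann_whitney_u,
    partial_correlation,
    roi_report,
    two_sample_t,
)
from ficdmap.group_stats import ClusterResult

from conftest import sphere_mesh


def cluster_of(vertex_ids):
    return ClusterResult(vertex_ids=np.asarray(vertex_ids), area=1.0, sign=-1, significant=True)


class TestExtraction:
    @pytest.fixture(scope="class")
    def cohort(self):
        mesh = sphere_mesh(2, 20.0)
        return make_cohort(mesh, CohortSpec(n_group_a=5, n_group_b=5, rng_seed=0))

    def test_constant_map_mean(self, cohort):
        vids = np.arange(10)
        c = cohort.with_maps(np.full_like(cohort.ficd_maps, 0.6))
        m = extract_cluster_metrics(cluster_of(vids), c)
        assert np.allclose(m.mean_ficd, 0.6)

    def test_gm_volume_is_sum_over_cluster(self, cohort):
        vids = np.arange(15)
        m = extract_cluster_metrics(cluster_of(vids), cohort)
        assert np.allclose(m.gm_volume, cohort.gm_maps[:, vids].sum(axis=1))

    def test_extraction_linear_in_maps(self, cohort):
        vids = np.arange(20)
        m1 = extract_cluster_metrics(cluster_of(vids), cohort)
        m3 = extract_cluster_metrics(cluster_of(vids), cohort.with_maps(3.0 * cohort.ficd_maps))
        assert np.allclose(m3.mean_ficd, 3.0 * m1.mean_ficd)

    def test_fiber_count_and_fa_from_cluster_seed(self):
        """A cluster over a straight bundle's footprint re-seeds the tracker:
        FN equals the surviving-track count and mean FA the bundle FA."""
        spec = PhantomSpec(
            grid_shape=(50, 50, 50),
            bundles=[Bundle(np.array([[-24.5, 0, 0], [24.5, 0, 0]]), radius=5.0, fa=0.8)],
            mesh_radius=15.0,
            mesh_subdivisions=3,
        )
        vol = make_tensor_phantom(spec)
        mesh = make_cortex_mesh(spec)
        cohort = make_cohort(mesh, CohortSpec(n_group_a=3, n_group_b=3, rng_seed=1))
        # cluster: vertices near the +x pole, inside the bundle footprint
        vids = np.flatnonzero(
            (mesh.vertices[:, 0] > 13.0) & (np.linalg.norm(mesh.vertices[:, 1:], axis=1) < 4.0)
        )
        m = extract_cluster_metrics(cluster_of(vids), cohort, vol=vol, params=TrackingParams())
        assert m.fiber_number is not None and m.fiber_number[0] > 0
        assert float(np.unique(m.fiber_number)[0]) == int(m.fiber_number[0])  # integer count
        assert m.mean_fiber_fa[0] == pytest.approx(0.8, abs=1e-6)


class TestGroupTests:
    def test_identical_samples_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(a, a)
        assert t == 0.0 and p == 1.0

    def test_exhaustive_pair_count_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        u, _ = mann_whitney_u(a, b)
        brute = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
        assert u == brute == 0.0
        t, _ = two_sample_t(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
        assert t == pytest.approx((a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3)), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=8),
           st.lists(st.integers(-50, 50), min_size=2, max_size=8))
    def test_swap_antisymmetry(self, xs, ys):
        a, b = np.asarray(xs, float), np.asarray(ys, float)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-9) and p1 == pytest.approx(p2, abs=1e-9)
        u1, _ = mann_whitney_u(a, b)
        u2, _ = mann_whitney_u(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b), abs=1e-9)

    def test_zero_variance_unequal_means(self):
        t, p = two_sample_t(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isinf(t) and t < 0 and p == 0.0


class TestPartialCorrelation:
    def test_perfect_dependence_survives_partialling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        r, p = partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0, abs=1e-12) and p < 1e-10

    def test_dependence_through_control_vanishes(self):
        # x and y both driven by z: partialling out z leaves only the small
        # independent noises, whose correlation is near zero
        rng = np.random.default_rng(1)
        z = rng.normal(size=500)
        x = 2.0 * z + rng.normal(scale=0.05, size=500)
        y = -1.0 * z + rng.normal(scale=0.05, size=500)
        r_raw = np.corrcoef(x, y)[0, 1]
        r, _ = partial_correlation(x, y, z)
        assert abs(r_raw) > 0.9 and abs(r) < 0.15

    def test_exactly_collinear_variable_rejected(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="residualization"):
            partial_correlation(x, z.copy(), z)

    def test_matches_three_correlation_closed_form(self):
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 20))
        r, _ = partial_correlation(x, y, z)
        rxy, rxz, ryz = np.corrcoef([x, y, z])[(0, 0, 1), (1, 2, 2)]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected, abs=1e-8)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            partial_correlation(np.zeros(3), np.zeros(3), np.zeros(3))


class TestRoiReport:
    @pytest.fixture(scope="class")
    def mesh(self):
        return sphere_mesh(3, 50.0)

    def test_severity_coupling_recovered(self, mesh):
        """Severity proportional to the (negative) cluster FiCD shift gives a
        negative severity-FiCD partial correlation in the affected group."""
        patch = contiguous_patch(mesh, 0, 80)
        cohort = make_cohort(
            mesh,
            CohortSpec(
                effect_vertices=patch,
                effect_size=-0.3,
                between_subject_sd=0.1,
                severity_coupling=-400.0,
                severity_noise_sd=2.0,
                rng_seed=3,
            ),
        )
        report = roi_report(cohort, [cluster_of(patch)])
        row = report[
            (report["analysis"] == "partial_corr[patient]") & (report["metric"] == "severity~mean_ficd")
        ].iloc[0]
        assert row["statistic"] < 0 and row["p"] < 0.05

    def test_null_cohort_small_correlations(self, mesh):
        cohort = make_cohort(mesh, CohortSpec(rng_seed=6))
        report = roi_report(cohort, [cluster_of(np.arange(60))])
        rows = report[report["analysis"].str.startswith("partial_corr")]
        assert (rows["p"] > 0.01).all()  # no spurious strong effect at this seed

    def test_row_count_deterministic(self, mesh):
        cohort = make_cohort(mesh, CohortSpec(rng_seed=7))
        clusters = [cluster_of(np.arange(30)), cluster_of(np.arange(40, 90))]
        report = roi_report(cohort, clusters)
        # per cluster: 2 group rows (no volume supplied) + 2 groups x 3 pairs
        assert len(report) == len(clusters) * (2 + 6)

    def test_normality_gate_switches_test(self, mesh):
        cohort = make_cohort(mesh, CohortSpec(rng_seed=8))
        # heavy-tailed severity forces the U test when the gate is active
        forced = roi_report(cohort, [cluster_of(np.arange(30))], force_test="u")
        assert (forced[forced["analysis"] == "group"]["test"] == "mann-whitney-u").all()
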