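"""Group mapping, mean shapes and vertex-wise Hotelling T²."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from foldmatch.groupstats import (GroupSample, hotelling_t2_map,
                                  longitudinal_group_analysis,
                                  map_group_to_reference, mean_shape)
from foldmatch.matching import MatchConfig
from foldmatch.mesh import TriangleMesh
from foldmatch.synthetic import icosphere


def brute_force_t2(a, b):
    """Dense textbook evaluation for one vertex: (n_a, 3) and (n_b, 3)."""
    n_a, n_b = len(a), len(b)
    diff = a.mean(0) - b.mean(0)
    s_pooled = ((n_a - 1) * np.cov(a.T) + (n_b - 1) * np.cov(b.T)) \
        / (n_a + n_b - 2)
    return n_a * n_b / (n_a + n_b) * diff @ np.linalg.inv(s_pooled) @ diff


class TestHotellingT2:
    def test_identical_samples_give_null(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 50, 3))
        sm = hotelling_t2_map(a, a.copy())
        assert np.allclose(sm.t2, 0.0, atol=1e-9)
        assert np.allclose(sm.p, 1.0)

    def test_matches_brute_force_on_hand_case(self):
        a = np.array([[1.0, 2.0, 0.5], [0.2, 1.1, -0.3], [-0.6, 2.5, 1.0]])
        b = np.array([[2.0, 0.4, 0.0], [1.5, 1.0, 0.8], [2.2, -0.1, 0.4]])
        sm = hotelling_t2_map(a[:, None, :], b[:, None, :])
        assert np.isclose(sm.t2[0], brute_force_t2(a, b), rtol=1e-10)
        # p from the exact F transform
        n, d = 6, 3
        f = (n - d - 1) / (d * (n - 2)) * sm.t2[0]
        assert np.isclose(sm.p[0], stats.f.sf(f, d, n - d - 1))

    def test_type_one_error_calibration(self):
        """Null rejection at alpha = 0.05 stays near nominal."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(20, 1000, 3))
        b = rng.normal(size=(20, 1000, 3))
        sm = hotelling_t2_map(a, b)
        assert 0.035 <= (sm.p < 0.05).mean() <= 0.065

    def test_power_at_cohort_size(self):
        """2 mm displacement, sigma 1 mm, n = 9 + 9 is well powered."""
        hits = []
        for r in range(300):
            rng = np.random.default_rng(r)
            a = rng.normal(0, 1, size=(9, 1, 3))
            b = rng.normal(0, 1, size=(9, 1, 3))
            b[:, :, 0] += 2.0
            hits.append(hotelling_t2_map(a, b).p[0] < 0.05)
        assert np.mean(hits) > 0.8

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 40, 3))
        b = rng.normal(size=(9, 40, 3)) + 0.5
        assert np.allclose(hotelling_t2_map(a, b).t2,
                           hotelling_t2_map(b, a).t2, rtol=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(7, 30, 3))
        b = rng.normal(size=(7, 30, 3)) + 1.0
        q = Rotation.from_euler("xyz", [20, -50, 10], degrees=True).as_matrix()
        t = np.array([4.0, -1.0, 2.0])
        sm1 = hotelling_t2_map(a, b)
        sm2 = hotelling_t2_map(a @ q.T + t, b @ q.T + t)
        assert np.allclose(sm1.t2, sm2.t2, atol=1e-6)

    def test_t2_monotone_in_displacement(self):
        rng = np.random.default_rng(5)
        base_a = rng.normal(size=(9, 200, 3))
        base_b = rng.normal(size=(9, 200, 3))
        medians = []
        for shift in (0.0, 1.0, 2.0):
            b = base_b.copy()
            b[:, :, 0] += shift
            medians.append(np.median(hotelling_t2_map(base_a, b).t2))
        assert medians[0] < medians[1] < medians[2]

    def test_small_sample_rejected(self):
        a = np.zeros((2, 5, 3))
        with pytest.raises(ValueError):
            hotelling_t2_map(a, a)

    def test_singular_covariance_ridged(self):
        # all subjects identical -> zero covariance; must not blow up
        a = np.tile(np.array([1.0, 2.0, 3.0]), (5, 4, 1))
        b = np.tile(np.array([1.5, 2.0, 3.0]), (5, 4, 1))
        sm = hotelling_t2_map(a, b)
        assert np.all(np.isfinite(sm.t2))
        assert sm.ridge_flagged.all()


class TestMeanShape:
    def _sample_from(self, meshes):
        coords = np.stack([m.vertices for m in meshes])
        return GroupSample(meshes[0].copy(), coords,
                           [f"s{i}" for i in range(len(meshes))])

    def test_identical_subjects(self, fixtures):
        mesh = fixtures["icosphere2"]
        sample = self._sample_from([mesh, mesh, mesh])
        assert np.allclose(mean_shape(sample).vertices, mesh.vertices)

    def test_two_spheres_average_radius(self):
        s8, s12 = icosphere(3, 8.0), icosphere(3, 12.0)
        mean = mean_shape(self._sample_from([s8, s12]))
        radii = np.linalg.norm(mean.vertices, axis=1)
        assert abs(np.median(radii) - 10.0) < 0.02 * 10.0

    def test_mean_of_folded_group_is_smoother(self):
        """Averaging independent folds cancels displacement variance."""
        from foldmatch.curvature import principal_curvatures
        from foldmatch.synthetic import FoldingSpec, generate_longitudinal_pair

        meshes = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            base = icosphere(3, 30.0)
            d = base.vertices / 30.0
            # independent random smooth folds per subject
            from foldmatch.synthetic import real_sph_harm
            f = sum(rng.normal(0, 1.2) * real_sph_harm(l, m, d)
                    for l in range(4, 7) for m in (-2, 1))
            meshes.append(TriangleMesh((30.0 + f)[:, None] * d, base.triangles))
        sample = self._sample_from(meshes)
        mean = mean_shape(sample)
        mean_abs_m = np.abs(principal_curvatures(mean).mean).mean()
        member_abs = np.mean([np.abs(principal_curvatures(m).mean).mean()
                              for m in meshes])
        assert mean_abs_m <= member_abs

    def test_needs_two_subjects(self, fixtures):
        mesh = fixtures["icosphere2"]
        with pytest.raises(ValueError):
            mean_shape(self._sample_from([mesh]))


class TestMapGroupToReference:
    def test_copies_of_reference_map_to_itself(self, fixtures):
        mesh = fixtures["icosphere3"]
        sample = map_group_to_reference(mesh, [mesh.copy(), mesh.copy()],
                                        MatchConfig(seed=0))
        assert sample.n_subjects == 2
        spread = np.linalg.norm(
            sample.coordinates - mesh.vertices[None], axis=2)
        assert np.median(spread) < 1e-6

    def test_rigid_motions_aligned_away(self, longitudinal_pair):
        early, _, _, _ = longitudinal_pair
        subjects = []
        for i, deg in enumerate(([10, 5, -8], [-20, 15, 30])):
            q = Rotation.from_euler("xyz", deg, degrees=True).as_matrix()
            subjects.append(TriangleMesh(
                early.vertices @ q.T + np.array([5.0 * i, -3, 2]),
                early.triangles))
        sample = map_group_to_reference(early, subjects, MatchConfig(seed=0))
        spread = np.linalg.norm(
            sample.coordinates - early.vertices[None], axis=2)
        assert np.median(spread) < 1.0

    def test_failing_subject_dropped_with_warning(self, fixtures, caplog):
        import logging

        mesh = fixtures["icosphere3"]
        bad = fixtures["two_components"]  # disconnected: matching must fail
        with caplog.at_level(logging.WARNING):
            sample = map_group_to_reference(
                mesh, [mesh.copy(), bad, mesh.copy()], MatchConfig(seed=0))
        assert sample.n_subjects == 2
        assert any("excluded" in r.message for r in caplog.records)


class TestLongitudinalGroupAnalysis:
    def _group(self, meshes):
        coords = np.stack([m.vertices for m in meshes])
        return GroupSample(meshes[0].copy(), coords,
                           [f"s{i}" for i in range(len(meshes))])

    def test_null_groups_nothing_significant(self):
        """Two groups drawn from one shape population: only nominal
        false positives may appear."""
        from foldmatch.synthetic import FoldingSpec, generate_longitudinal_pair

        rng = np.random.default_rng(0)
        base, _, _, _ = generate_longitudinal_pair(
            FoldingSpec(seed=0, vertex_noise_sd=0.0), subdivision=3)
        n = base.n_vertices
        meshes = [TriangleMesh(base.vertices + rng.normal(0, 0.2, (n, 3)),
                               base.triangles) for _ in range(12)]
        early = self._group(meshes[:6])
        late = self._group(meshes[6:])
        stat, _, _ = longitudinal_group_analysis(early, late,
                                                 MatchConfig(seed=0))
        assert (stat.p < 0.05).mean() < 0.12   # nominal false positives only

    def test_paired_statistic_available(self):
        rng = np.random.default_rng(1)
        base = icosphere(2, 30.0)
        meshes = [TriangleMesh(base.vertices + rng.normal(0, 0.3, (162, 3)),
                               base.triangles) for _ in range(6)]
        early, late = self._group(meshes[:3] + meshes[:3]), \
            self._group(meshes[3:] + meshes[3:])
        stat, _, _ = longitudinal_group_analysis(early, late,
                                                 MatchConfig(seed=0),
                                                 paired=True)
        assert np.all(np.isfinite(stat.t2))
        assert np.all((stat.p > 0) & (stat.p <= 1))
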