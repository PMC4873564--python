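"""Curvature estimation and longitudinal change measures."""

import numpy as np
import pytest

from foldmatch import curvature as curv
from foldmatch.cpd import Correspondence
from foldmatch.mesh import TriangleMesh, enclosed_volume, surface_area, \
    vertex_areas
from foldmatch.synthetic import FoldingSpec, generate_longitudinal_pair, \
    icosphere


@pytest.fixture(scope="module")
def sphere4():
    return icosphere(4, radius=10.0)


@pytest.fixture(scope="module")
def sphere_field(sphere4):
    return curv.principal_curvatures(sphere4, ring=2)


class TestPrincipalCurvatures:
    def test_sphere_curvatures_match_inverse_radius(self, sphere_field):
        assert abs(np.median(sphere_field.k1) - 0.1) < 0.005
        assert abs(np.median(sphere_field.k2) - 0.1) < 0.005

    def test_sphere_mean_curvature_positive_convention(self, sphere_field):
        # outward-convex surface (a gyral cap everywhere) must be positive
        assert np.all(sphere_field.mean > 0)

    def test_cylinder_principal_curvatures(self, fixtures):
        mesh = fixtures["cylinder"]  # radius 5, height 20
        field = curv.principal_curvatures(mesh, ring=2)
        # restrict to the tube portion away from the caps
        tube = np.abs(mesh.vertices[:, 2]) < 5.0
        radial = np.linalg.norm(mesh.vertices[:, :2], axis=1) > 4.9
        sel = tube & radial
        assert abs(np.median(field.k1[sel]) - 0.2) < 0.02
        assert np.median(np.abs(field.k2[sel])) < 0.02

    def test_saddle_negative_gaussian(self, fixtures):
        mesh = fixtures["saddle"]
        field = curv.principal_curvatures(mesh, ring=2)
        center = np.argmin(np.linalg.norm(mesh.vertices[:, :2], axis=1))
        assert field.gaussian[center] < 0

    def test_total_curvature_identity(self, sphere_field):
        t = sphere_field.total
        assert np.allclose(t, 4 * sphere_field.mean ** 2
                           - 2 * sphere_field.gaussian, atol=1e-9)

    def test_gauss_bonnet(self, sphere4, sphere_field):
        total = (sphere_field.gaussian * vertex_areas(sphere4)).sum()
        assert abs(total - 4 * np.pi) < 0.05 * 4 * np.pi

    def test_sphere_bending_energy_8pi(self, sphere4, sphere_field):
        e = curv.total_bending_energy(sphere4, sphere_field)
        assert abs(e - 8 * np.pi) < 0.03 * 8 * np.pi

    def test_bending_energy_converges_with_subdivision(self):
        errs = []
        for s in (2, 3, 4):
            mesh = icosphere(s, radius=10.0)
            field = curv.principal_curvatures(mesh, ring=2)
            errs.append(abs(curv.total_bending_energy(mesh, field) - 8 * np.pi))
        assert errs[-1] < errs[0]

    def test_gaussian_noisier_than_mean_on_jittered_sphere(self):
        mesh = icosphere(3, radius=10.0)
        rng = np.random.default_rng(0)
        jittered = TriangleMesh(
            mesh.vertices + rng.normal(0, 0.1, mesh.vertices.shape),
            mesh.triangles)
        field = curv.principal_curvatures(jittered, ring=2)
        rel_m = np.abs(field.mean - 0.1) / 0.1
        rel_g = np.abs(field.gaussian - 0.01) / 0.01
        assert np.median(rel_g) > np.median(rel_m)


class TestVolumeNormalize:
    def test_reference_equal_subject_is_identity(self):
        v = np.array([0.1, -0.2])
        assert np.allclose(curv.volume_normalize(v, 5.0, 5.0), v)

    def test_cube_root_of_ratio(self):
        # ratio 8 -> length factor 2: curvature values double
        assert np.allclose(curv.volume_normalize(np.ones(3), 8.0, 1.0), 2.0)

    def test_scaling_invariance(self):
        s1, s2 = icosphere(3, 10.0), icosphere(3, 25.0)
        f1 = curv.principal_curvatures(s1)
        f2 = curv.principal_curvatures(s2)
        n1 = curv.volume_normalize(f1.mean, enclosed_volume(s1), 1000.0)
        n2 = curv.volume_normalize(f2.mean, enclosed_volume(s2), 1000.0)
        assert np.allclose(n1, n2, atol=1e-6)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            curv.volume_normalize(np.ones(2), -1.0, 1.0)


class TestMapScalar:
    def test_identity_and_constant(self):
        corr = Correspondence(np.array([2, 0, 1]))
        assert np.allclose(curv.map_scalar(corr, np.array([5.0, 5, 5])), 5.0)
        ident = Correspondence(np.arange(3))
        vals = np.array([1.0, 2, 3])
        assert np.array_equal(curv.map_scalar(ident, vals), vals)

    def test_patch_field_pullback(self, longitudinal_pair):
        early, late, gt, labels = longitudinal_pair
        field = (labels >= 0).astype(float)
        pulled = curv.map_scalar(gt, field)
        assert (pulled == field).mean() >= 0.9


class TestCurvatureChange:
    def test_identical_meshes_zero_change(self, fixtures):
        mesh = fixtures["icosphere3"]
        f = curv.principal_curvatures(mesh)
        dm, dg = curv.curvature_change(f, f, Correspondence.identity(
            mesh.n_vertices), 100.0, 100.0)
        assert np.allclose(dm, 0.0)
        assert np.allclose(dg, 0.0)

    def test_pure_growth_gives_zero_change(self):
        """Concentric spheres: normalization removes uniform scale."""
        s1, s2 = icosphere(3, 10.0), icosphere(3, 20.0)
        f1, f2 = curv.principal_curvatures(s1), curv.principal_curvatures(s2)
        dm, dg = curv.curvature_change(
            f1, f2, Correspondence.identity(s1.n_vertices),
            enclosed_volume(s1), enclosed_volume(s2))
        assert np.abs(dm).max() < 1e-3          # ~1/mm scale is 0.1
        assert np.abs(dg).max() < 1e-4

    def test_patch_folding_contrast(self, longitudinal_pair):
        early, late, gt, labels = longitudinal_pair
        fe = curv.principal_curvatures(early)
        fl = curv.principal_curvatures(late)
        dm, _ = curv.curvature_change(fe, fl, gt, enclosed_volume(early),
                                      enclosed_volume(late))
        inside = labels >= 0
        assert np.abs(dm[inside]).mean() > 3 * np.abs(dm[~inside]).mean()


class TestLocalAreaChange:
    def test_identity_ratio_one(self, fixtures):
        mesh = fixtures["icosphere3"]
        r = curv.local_area_change(mesh, mesh,
                                   Correspondence.identity(mesh.n_vertices))
        assert np.allclose(r, 1.0)

    def test_uniform_scaling_squares(self):
        s1, s2 = icosphere(3, 10.0), icosphere(3, 15.0)
        r = curv.local_area_change(s1, s2,
                                   Correspondence.identity(s1.n_vertices))
        assert abs(np.median(r) - 1.5 ** 2) < 0.05 * 1.5 ** 2

    def test_area_conservation(self, longitudinal_pair):
        early, late, gt, _ = longitudinal_pair
        r = curv.local_area_change(early, late, gt)
        total = (r * vertex_areas(early)).sum()
        assert abs(total - surface_area(late)) < 0.1 * surface_area(late)


class TestBendingEnergyChange:
    def test_identical_meshes_zero(self, fixtures):
        mesh = fixtures["icosphere3"]
        f = curv.principal_curvatures(mesh)
        ident = Correspondence.identity(mesh.n_vertices)
        ratio = curv.local_area_change(mesh, mesh, ident)
        de = curv.bending_energy_change(f, f, ident, ratio, mesh)
        assert np.allclose(de, 0.0, atol=1e-12)

    def test_sphere_growth_total_change_vanishes(self):
        """Total bending energy of any sphere is 8*pi, so growth alone
        moves no energy in total."""
        s1, s2 = icosphere(3, 10.0), icosphere(3, 17.0)
        f1, f2 = curv.principal_curvatures(s1), curv.principal_curvatures(s2)
        ident = Correspondence.identity(s1.n_vertices)
        ratio = curv.local_area_change(s1, s2, ident)
        de = curv.bending_energy_change(f1, f2, ident, ratio, s1)
        assert abs(de.sum()) < 0.03 * 8 * np.pi

    def test_patch_folding_dominates(self, longitudinal_pair):
        early, late, gt, labels = longitudinal_pair
        fe = curv.principal_curvatures(early)
        fl = curv.principal_curvatures(late)
        ratio = curv.local_area_change(early, late, gt)
        de = curv.bending_energy_change(fe, fl, gt, ratio, early)
        inside = labels >= 0
        assert de[inside].sum() > 0
        assert de[inside].sum() > 3 * abs(de[~inside].sum())

    def test_alternative_ordering_available(self, fixtures):
        mesh = fixtures["icosphere3"]
        f = curv.principal_curvatures(mesh)
        ident = Correspondence.identity(mesh.n_vertices)
        ratio = curv.local_area_change(mesh, mesh, ident)
        de = curv.bending_energy_change(f, f, ident, ratio, mesh,
                                        ordering="divide")
        assert np.allclose(de, 0.0, atol=1e-12)
        with pytest.raises(ValueError):
            curv.bending_energy_change(f, f, ident, ratio, mesh, ordering="x")
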