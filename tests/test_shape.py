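"""Seed-sphere shape function and planar-convex parameterization."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from hepatoseg.shape import (ClosedSurface, ShapeMap, align_principal_axes,
                             candidate_directions, compare_shapes,
                             parameterize_surface, select_convexity_planes,
                             shape_function, uncertain_regions)
from conftest import grid_mm, slab_surface, sphere_surface


def mc_ball_fraction(surface, point, r, n_samples=1_000_000, seed=0):
    """Independent Monte-Carlo estimate of the ball-interior volume fraction."""
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_samples, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    d *= rng.random((n_samples, 1)) ** (1 / 3) * r
    sp = np.asarray(surface.spacing)
    coords = (np.asarray(point) + d) / sp - 0.5
    vals = ndi.map_coordinates(surface.occupancy.astype(float), coords.T, order=1)
    est = vals.mean()
    sigma = np.sqrt(max(est * (1 - est), 1e-12) / n_samples)
    return est, sigma


class TestShapeFunction:
    def test_flat_boundary_gives_half(self):
        s = slab_surface()
        assert shape_function(s, (20.0, 20.0, 20.0), 4.0) == pytest.approx(0.5, abs=0.02)

    def test_quarter_space_edge_gives_quarter(self):
        s = slab_surface()
        # point on the edge where the z = 20 face meets the y = 38 face
        assert shape_function(s, (20.0, 38.0, 20.0), 4.0) == pytest.approx(0.25, abs=0.02)

    def test_sphere_matches_monte_carlo_within_3_sigma(self):
        s = sphere_surface(n=44, center=22.0, radius=16.0)
        p = (22.0 + 16.0, 22.0, 22.0)
        v = shape_function(s, p, 4.0)
        mc, sigma = mc_ball_fraction(s, p, 4.0)
        assert abs(v - mc) <= 3 * sigma + 1e-3   # quadrature discretization slack

    def test_sphere_agrees_with_lens_closed_form(self):
        # ball-ball intersection closed form as a coarse cross-check (the
        # voxelized boundary flattens curvature at the one-voxel scale)
        R, r = 16.0, 4.0
        s = sphere_surface(n=44, center=22.0, radius=R)
        v = shape_function(s, (22.0 + R, 22.0, 22.0), r)
        d = R
        lens = (np.pi * (R + r - d) ** 2
                * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
                ) / (12 * d)
        frac = lens / (4 / 3 * np.pi * r**3)
        assert v == pytest.approx(frac, abs=0.06)

    def test_rigid_motion_invariance_90_degree(self):
        x, y, z = grid_mm(40)
        occ = ((x - 20) / 12) ** 2 + ((y - 20) / 8) ** 2 + ((z - 16) / 9) ** 2 <= 1
        s = ClosedSurface(occ)
        v = shape_function(s, (32.0, 20.0, 16.0), 3.0)
        rot = ClosedSurface(np.rot90(occ, axes=(0, 1)))
        # the +x surface point maps to +y under this rotation
        v_rot = shape_function(rot, (20.0, 32.0, 16.0), 3.0)
        assert v_rot == pytest.approx(v, abs=0.02)

    def test_scale_covariance(self):
        # both spheres resolved well enough that voxel flattening is small
        small = sphere_surface(n=44, center=22.0, radius=16.0)
        big = sphere_surface(n=88, center=44.0, radius=32.0)
        v_small = shape_function(small, (38.0, 22.0, 22.0), 8.0)
        v_big = shape_function(big, (76.0, 44.0, 44.0), 16.0)
        assert v_big == pytest.approx(v_small, abs=0.02)

    def test_point_off_boundary_rejected(self):
        s = sphere_surface()
        with pytest.raises(ValueError, match="boundary"):
            shape_function(s, (22.0, 22.0, 22.0), 4.0)   # center, far inside

    def test_subvoxel_radius_rejected(self):
        s = sphere_surface()
        with pytest.raises(ValueError, match="radius"):
            shape_function(s, (38.0, 22.0, 22.0), 0.5)


class TestDirections:
    def test_thirty_two_unit_vectors_well_separated(self):
        d = candidate_directions()
        assert d.shape == (32, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        dots = d @ d.T
        np.fill_diagonal(dots, -1.0)
        min_sep = np.degrees(np.arccos(dots.max()))
        assert min_sep > 10.0

    def test_hemisphere_folding_removes_all_antipodal_pairs(self):
        f = candidate_directions(fold_hemisphere=True)
        assert len(f) == 16
        for i, a in enumerate(f):
            for b in f[i + 1:]:
                assert not np.allclose(a, -b, atol=1e-9)


class TestPrincipalAxes:
    def test_axis_aligned_ellipsoid_gives_identity_up_to_sign(self):
        x, y, z = grid_mm(80)
        occ = ((x - 40) / 30) ** 2 + ((y - 40) / 20) ** 2 + ((z - 40) / 10) ** 2 <= 1
        t = align_principal_axes(ClosedSurface(occ))
        assert np.allclose(np.abs(t.rotation), np.eye(3), atol=0.02)

    def test_rotation_recovery_within_one_degree(self):
        Rz = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        x, y, z = grid_mm(80)
        pts = np.stack([x - 40, y - 40, z - 40], axis=-1) @ Rz
        occ = ((pts[..., 0] / 30) ** 2 + (pts[..., 1] / 20) ** 2
               + (pts[..., 2] / 10) ** 2 <= 1)
        t = align_principal_axes(ClosedSurface(occ))
        expected = Rz @ np.array([1.0, 0.0, 0.0])   # world direction of long axis
        angle = np.degrees(np.arccos(min(abs(t.rotation[0] @ expected), 1.0)))
        assert angle < 1.0

    def test_sphere_is_deterministic(self):
        s = sphere_surface()
        t1 = align_principal_axes(s)
        t2 = align_principal_axes(s)
        assert np.array_equal(t1.rotation, t2.rotation)


class TestConvexityPlanes:
    def test_ellipsoid_scores_one_and_tie_breaks_to_x(self):
        x, y, z = grid_mm(64)
        occ = ((x - 32) / 24) ** 2 + ((y - 32) / 18) ** 2 + ((z - 32) / 12) ** 2 <= 1
        ps = select_convexity_planes(ClosedSurface(occ))
        assert ps.score == 1.0
        assert np.allclose(ps.normal, [1, 0, 0])

    def test_dumbbell_bridge_axis_wins(self):
        x, y, z = grid_mm(64)
        occ = ((x - 18) ** 2 + (y - 32) ** 2 + (z - 32) ** 2 <= 100)
        occ |= ((x - 46) ** 2 + (y - 32) ** 2 + (z - 32) ** 2 <= 100)
        occ |= ((x >= 18) & (x <= 46) & ((y - 32) ** 2 + (z - 32) ** 2 <= 9))
        ps = select_convexity_planes(ClosedSurface(occ), directions=np.eye(3))
        assert np.allclose(ps.normal, [1, 0, 0])
        assert ps.score == 1.0
        # transverse slicing cuts two spheres -> worse than the bridge axis
        ps_y = select_convexity_planes(ClosedSurface(occ),
                                       directions=np.array([[0.0, 1.0, 0.0]]))
        assert ps_y.score > 1.0

    def test_torus_has_no_planar_convex_direction_but_returns_minimizer(self):
        x, y, z = grid_mm(64)
        rho = np.sqrt((x - 32) ** 2 + (y - 32) ** 2)
        occ = (rho - 18) ** 2 + (z - 32) ** 2 <= 36
        ps = select_convexity_planes(ClosedSurface(occ), directions=np.eye(3))
        assert ps.score > 1.0


class TestParameterization:
    def test_cylinder_four_divisions_are_equally_spaced(self):
        x, y, z = grid_mm(48)
        occ = (x > 6) & (x < 42) & ((y - 24) ** 2 + (z - 24) ** 2 <= 15**2)
        ps = select_convexity_planes(ClosedSurface(occ))   # tie rule -> x axis
        par = parameterize_surface(ps, 4)
        assert par.points.shape == (len(ps.offsets), 4, 3)
        p0 = par.points[len(ps.offsets) // 2]
        chords = [np.linalg.norm(p0[(i + 1) % 4] - p0[i]) for i in range(4)]
        assert (max(chords) - min(chords)) / np.mean(chords) < 0.02

    def test_sphere_sampling_is_near_uniform(self):
        s = sphere_surface(n=48, center=24.0, radius=16.0)
        ps = select_convexity_planes(s, n_planes=20)
        par = parameterize_surface(ps, 36)
        pts = par.points.reshape(-1, 3)
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        assert nn.std() / nn.mean() < 0.5

    def test_points_lie_on_the_surface(self):
        s = sphere_surface(n=48, center=24.0, radius=16.0)
        ps = select_convexity_planes(s, n_planes=12)
        par = parameterize_surface(ps, 12)
        radii = np.linalg.norm(par.points.reshape(-1, 3) - 24.0, axis=1)
        assert np.all(np.abs(radii - 16.0) <= 1.0)   # within half a voxel + contour tol

    def test_multi_component_slice_rejected(self):
        x, y, z = grid_mm(64)
        occ = ((x - 18) ** 2 + (y - 32) ** 2 + (z - 32) ** 2 <= 100)
        occ |= ((x - 46) ** 2 + (y - 32) ** 2 + (z - 32) ** 2 <= 100)
        occ |= ((x >= 18) & (x <= 46) & ((y - 32) ** 2 + (z - 32) ** 2 <= 9))
        ps = select_convexity_planes(ClosedSurface(occ),
                                     directions=np.array([[0.0, 1.0, 0.0]]))
        with pytest.raises(ValueError, match="components"):
            parameterize_surface(ps, 8)


@pytest.fixture(scope="module")
def sphere_vs_dented():
    x, y, z = grid_mm(48)
    occ = (x - 24) ** 2 + (y - 24) ** 2 + (z - 24) ** 2 <= 16**2
    dent = occ & ~((x - 24) ** 2 + (y - 24) ** 2 + (z - 40) ** 2 <= 7**2)
    sa, sb = ClosedSurface(occ), ClosedSurface(dent)
    pa = select_convexity_planes(sa, directions=np.eye(3), n_planes=16)
    pb = select_convexity_planes(sb, directions=np.eye(3), n_planes=16)
    return (parameterize_surface(pa, 16), sa,
            parameterize_surface(pb, 16), sb)


class TestCompareAndRegions:
    def test_self_comparison_is_zero_discrepancy(self, sphere_vs_dented):
        para, sa, _, _ = sphere_vs_dented
        sm = compare_shapes(para, sa, para, sa, r=3.0)
        assert np.all(sm.s_a == sm.s_b)

    def test_normalized_map_attains_zero_and_one(self, sphere_vs_dented):
        para, sa, parb, sb = sphere_vs_dented
        sm = compare_shapes(para, sa, parb, sb, r=3.0)
        assert sm.s_norm.min() == 0.0
        assert sm.s_norm.max() == 1.0

    def test_dent_localizes_the_map_maximum(self, sphere_vs_dented):
        para, sa, parb, sb = sphere_vs_dented
        sm = compare_shapes(para, sa, parb, sb, r=3.0)
        pi, di = np.unravel_index(np.argmax(sm.s_norm), sm.s_norm.shape)
        hit = parb.points[pi, di]
        assert np.linalg.norm(hit - np.array([24.0, 24.0, 40.0])) <= 8.5

    def test_symmetry_of_averaged_map(self, sphere_vs_dented):
        para, sa, parb, sb = sphere_vs_dented
        ab = compare_shapes(para, sa, parb, sb, r=3.0)
        ba = compare_shapes(parb, sb, para, sa, r=3.0)
        assert np.allclose(ab.s_mean, ba.s_mean)

    def _fake_map(self, param, norm):
        return ShapeMap(s_a=norm, s_b=norm, s_mean=norm, s_norm=norm,
                        seed_radius=3.0)

    def test_all_below_threshold_gives_no_regions(self, sphere_vs_dented):
        para = sphere_vs_dented[0]
        norm = np.full(para.points.shape[:2], 0.2)
        ur = uncertain_regions(self._fake_map(para, norm), para)
        assert ur.n_regions == 0

    def test_two_patches_give_two_seeded_regions(self, sphere_vs_dented):
        para = sphere_vs_dented[0]
        norm = np.zeros(para.points.shape[:2])
        norm[2:4, 2:5] = 0.9
        norm[10:12, 8:11] = 0.8
        ur = uncertain_regions(self._fake_map(para, norm), para)
        assert ur.n_regions == 2
        for k, seed in enumerate(ur.seeds_mm, start=1):
            members = para.points[ur.labels == k]
            assert any(np.allclose(seed, m) for m in members)

    def test_threshold_is_inclusive_at_exactly_half(self, sphere_vs_dented):
        para = sphere_vs_dented[0]
        norm = np.zeros(para.points.shape[:2])
        norm[5, 5] = 0.5
        ur = uncertain_regions(self._fake_map(para, norm), para)
        assert ur.n_regions == 1
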