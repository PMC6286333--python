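"""Deviation extraction, grid resampling, and the asymmetry index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from backsym.asymmetry import (
    ResampledCloud,
    align_union_axes,
    asymmetry_index,
    colormap_deviations,
    effective_and_valid_sets,
    grid_deviations,
    resample_on_grid,
)
from backsym.geometry import PointCloud, estimate_normals_and_curvature
from backsym.synthetic import TorsoSpec, generate_scan
from backsym import run_pipeline


def _plane_cloud(z=0.0, half=30.0, spacing=3.0, with_normals=True):
    g = np.arange(-half, half + 1e-9, spacing)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    cloud = PointCloud(np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)]))
    return estimate_normals_and_curvature(cloud, radius=8.0) if with_normals else cloud


def _brute_force_ray_distance(origin, direction, vertices, triangles, gate):
    """Independent oracle: solve each triangle's parametric system directly."""
    best = np.inf
    for tri in triangles:
        v0, v1, v2 = vertices[tri]
        M = np.column_stack([-direction, v1 - v0, v2 - v0])
        if abs(np.linalg.det(M)) < 1e-12:
            continue
        t, u, v = np.linalg.solve(M, origin - v0)
        if u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12:
            best = min(best, abs(t))
    return best if best <= gate else np.nan


class TestColormapDeviations:
    def test_identical_planes_zero(self):
        plane = _plane_cloud()
        res = colormap_deviations(plane, plane, gate=100.0)
        assert res.valid_mask.all()
        np.testing.assert_allclose(res.distances, 0.0, atol=1e-9)

    def test_uniform_normal_offset(self):
        plane = _plane_cloud()
        # +2 mm along every normal (0, 0, -1)
        shifted = PointCloud(plane.points + np.array([0.0, 0.0, -2.0]))
        res = colormap_deviations(plane, shifted, gate=100.0)
        np.testing.assert_allclose(res.distances[res.valid_mask], 2.0, atol=1e-9)
        assert res.valid_mask.mean() > 0.9

    def test_matches_brute_force_intersection_oracle(self, wavy_surface):
        thin = wavy_surface.select(np.arange(0, len(wavy_surface), 7))
        target = PointCloud(wavy_surface.points + np.array([0.0, 1.0, -3.0]))
        res = colormap_deviations(thin, target, gate=100.0)
        for i in range(0, len(thin), 5):
            oracle = _brute_force_ray_distance(
                thin.points[i], thin.normals[i], res.vertices, res.triangles, res.gate
            )
            if math.isnan(oracle):
                assert not res.valid_mask[i]
            else:
                assert res.distances[i] == pytest.approx(oracle, abs=1e-9)

    def test_gate_drops_distant_surface(self):
        plane = _plane_cloud()
        far = PointCloud(plane.points + np.array([0.0, 0.0, 150.0]))
        res = colormap_deviations(plane, far, gate=100.0)
        assert not res.valid_mask.any()


class TestAlignUnionAxes:
    def test_relative_pose_preserved(self, wavy_surface):
        other = PointCloud(wavy_surface.points + np.array([0.0, 0.0, 2.0]))
        P7, P7r, _ = align_union_axes(wavy_surface, other)
        d_before = np.linalg.norm(wavy_surface.points[:50] - other.points[:50], axis=1)
        d_after = np.linalg.norm(P7.points[:50] - P7r.points[:50], axis=1)
        np.testing.assert_allclose(d_before, d_after, atol=1e-9)

    def test_union_covariance_diagonal(self, wavy_surface):
        other = PointCloud(wavy_surface.points + np.array([1.0, 0.5, 2.0]))
        P7, P7r, _ = align_union_axes(wavy_surface, other)
        union = np.vstack([P7.points, P7r.points])
        cov = np.cov(union.T)
        off = np.abs(cov - np.diag(np.diag(cov))).sum()
        assert off < 1e-6 * np.trace(cov)


class TestResampleOnGrid:
    def test_plane_resamples_exactly(self):
        plane = _plane_cloud(z=7.0)
        res = resample_on_grid(plane, 3.0, 3.0, 25.0)
        assert res.effective.any()
        np.testing.assert_allclose(res.points[res.effective][:, 2], 7.0, atol=1e-9)

    def test_sphere_cap_matches_analytic_height(self):
        R, cz = 200.0, 500.0
        g = np.arange(-60.0, 60.1, 3.0)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        z = cz - np.sqrt(R**2 - gx**2 - gy**2)
        cloud = estimate_normals_and_curvature(
            PointCloud(np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])), radius=25.0
        )
        res = resample_on_grid(cloud, 3.0, 3.0, 25.0)
        cap = res.effective & (np.linalg.norm(res.points[..., :2], axis=-1) < 40.0)
        pts = res.points[cap]
        analytic = cz - np.sqrt(R**2 - pts[:, 0] ** 2 - pts[:, 1] ** 2)
        assert np.abs(pts[:, 2] - analytic).max() < 0.1

    def test_isolated_node_ineffective(self):
        lone = PointCloud(np.array([[50.0, 50.0, 3.0], [50.0, 53.0, 3.0], [53.0, 50.0, 3.0]]))
        res = resample_on_grid(estimate_normals_and_curvature(lone, 10.0), 3.0, 3.0, 10.0,
                               grid_bounds=(0, 20, 0, 20))
        # nodes far from the three points stay ineffective
        assert not res.effective[0, 0]
        assert res.effective.sum() < 25


def _mask_cloud(mask: np.ndarray, z=0.0, dx=3.0, dy=3.0, l0=0, m0=0) -> ResampledCloud:
    L, M = mask.shape
    pts = np.full((L, M, 3), np.nan)
    ls, ms = np.meshgrid(np.arange(L) + l0, np.arange(M) + m0, indexing="ij")
    pts[..., 0] = ls * dx
    pts[..., 1] = ms * dy
    pts[..., 2] = z
    pts[~mask] = np.nan
    return ResampledCloud(l0=l0, m0=m0, dx=dx, dy=dy, points=pts, effective=mask.copy())


class TestEffectiveAndValidSets:
    def test_alpha_one_keeps_all_effective(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 15)) > 0.3
        G_E, G_v = effective_and_valid_sets(_mask_cloud(mask), _mask_cloud(mask), alpha=1.0)
        np.testing.assert_array_equal(G_E, G_v)

    def test_column_range_arithmetic(self):
        mask = np.zeros((1, 101), dtype=bool)
        mask[0, :] = True
        _, G_v = effective_and_valid_sets(_mask_cloud(mask), _mask_cloud(mask), alpha=0.9)
        valid_m = np.flatnonzero(G_v[0])
        assert valid_m.min() == 5 and valid_m.max() == 95

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 100), alpha=st.floats(0.3, 1.0))
    def test_matches_per_column_oracle(self, seed, alpha):
        rng = np.random.default_rng(seed)
        m1 = rng.random((8, 20)) > 0.4
        m2 = rng.random((8, 20)) > 0.4
        if not (m1 & m2).any():
            return
        try:
            G_E, G_v = effective_and_valid_sets(_mask_cloud(m1), _mask_cloud(m2), alpha)
        except ValueError:
            return
        for l in range(8):
            rows = np.flatnonzero(G_E[l])
            expected = np.zeros(20, dtype=bool)
            if len(rows):
                m_min, m_max = rows.min(), rows.max()
                margin = 0.5 * (1 - alpha) * (m_max - m_min)
                for m in rows:
                    expected[m] = m_min + margin <= m <= m_max - margin
            np.testing.assert_array_equal(G_v[l], expected)

    def test_alpha_monotonicity_of_valid_count(self):
        rng = np.random.default_rng(9)
        mask = rng.random((12, 25)) > 0.25
        counts = []
        for alpha in (0.5, 0.7, 0.9, 1.0):
            _, G_v = effective_and_valid_sets(_mask_cloud(mask), _mask_cloud(mask), alpha)
            counts.append(G_v.sum())
        assert counts == sorted(counts)


class TestGridDeviations:
    def test_identical_grids_zero(self):
        mask = np.ones((10, 10), dtype=bool)
        c = _mask_cloud(mask)
        _, G_v = effective_and_valid_sets(c, c, 1.0)
        D, G_v = grid_deviations(c, c, G_v, r8=10.0)
        np.testing.assert_allclose(D[G_v], 0.0, atol=1e-12)

    def test_parallel_planes_constant_deviation(self):
        mask = np.ones((10, 10), dtype=bool)
        lo, hi = _mask_cloud(mask, z=0.0), _mask_cloud(mask, z=3.0)
        _, G_v = effective_and_valid_sets(lo, hi, 1.0)
        D, G_v = grid_deviations(lo, hi, G_v, r8=10.0)
        np.testing.assert_allclose(D[G_v], 3.0, atol=1e-9)

    def test_curved_grid_matches_direct_formula(self):
        mask = np.ones((15, 15), dtype=bool)
        base = _mask_cloud(mask)
        base.points[..., 2] = 0.01 * base.points[..., 0] ** 2
        other = _mask_cloud(mask)
        other.points[..., 2] = base.points[..., 2] + 2.0
        _, G_v = effective_and_valid_sets(base, other, 1.0)
        D, G_v = grid_deviations(base, other, G_v, r8=10.0)
        eff = base.points[base.effective]
        for l, m in np.argwhere(G_v)[::7]:
            p = base.points[l, m]
            nb = eff[np.linalg.norm(eff - p, axis=1) <= 10.0]
            centered = nb - nb.mean(axis=0)
            n = np.linalg.eigh(centered.T @ centered)[1][:, 0]
            assert D[l, m] == pytest.approx(abs(n @ (other.points[l, m] - p)), abs=1e-9)


class TestAsymmetryIndex:
    def test_trivial_means(self):
        D = np.array([[0.0, 0.0, 0.0]])
        assert asymmetry_index(D, np.ones_like(D, dtype=bool)) == 0.0
        D = np.array([[1.0, 2.0, 3.0]])
        assert asymmetry_index(D, np.ones_like(D, dtype=bool)) == 2.0

    def test_linearity_and_exactness(self):
        rng = np.random.default_rng(12)
        D = rng.uniform(0, 5, (20, 20))
        G = rng.random((20, 20)) > 0.4
        i1 = asymmetry_index(D, G)
        assert asymmetry_index(3.0 * D, G) == pytest.approx(3.0 * i1, rel=1e-12)
        exact = math.fsum(D[G]) / G.sum()
        assert i1 == pytest.approx(exact, rel=1e-12)

    def test_empty_valid_set_raises(self):
        with pytest.raises(ValueError):
            asymmetry_index(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool))


class TestPipeline:
    def test_symmetric_torso_index_near_zero(self, symmetric_result):
        assert symmetric_result.i_asym < 0.05
        assert symmetric_result.valid_count > 1000

    def test_index_strictly_increases_with_hump_amplitude(self, hump_results):
        amps = sorted(hump_results)
        values = [hump_results[a].i_asym for a in amps]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_mirrored_scan_same_index(self, hump_results, fast_config):
        scan = generate_scan(TorsoSpec(pitch=5.0, hump_amplitude=6.0))
        mirrored = PointCloud(scan.points * np.array([1.0, -1.0, 1.0]))
        res = run_pipeline(mirrored, fast_config)
        ref = hump_results[6.0].i_asym
        assert res.i_asym == pytest.approx(ref, rel=0.02)

    def test_small_pose_tilt_leaves_index_stable(self, hump_results, fast_config):
        scan = generate_scan(TorsoSpec(pitch=5.0, hump_amplitude=6.0, rot_x=4.0, rot_y=3.0))
        res = run_pipeline(scan, fast_config)
        assert res.i_asym == pytest.approx(hump_results[6.0].i_asym, rel=0.05)

    def test_valid_count_monotone_in_alpha(self, symmetric_result):
        grid = symmetric_result.grid
        counts = []
        for alpha in (0.5, 0.7, 0.9, 1.0):
            _, G_v = effective_and_valid_sets(grid.P8, grid.P8r, alpha)
            counts.append(int(G_v.sum()))
        assert counts == sorted(counts)
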