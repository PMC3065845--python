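import math

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import lamina3d as l3
from lamina3d.features import (
    MeasurementParams,
    average_normalized_intensity,
    clip_outliers,
    convex_hull_area,
    curvature_field,
    intensity_curvature_correlation,
    intensity_skewness,
    normalize_intensity,
    normalized_curvature,
    spatial_maps,
    streaming_skewness,
)
from lamina3d.volume_io import LaminaMask, VoxelGrid3D


def spherical_field(n, R, width=3.0):
    """Spherically symmetric ridge field and a one-voxel-thick shell mask."""
    c = (n - 1) / 2
    z, y, x = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
    r = np.sqrt(z**2 + y**2 + x**2)
    f = np.exp(-((r - R) ** 2) / (2 * width**2))
    return VoxelGrid3D(f, (1.0, 1.0, 1.0)), LaminaMask(np.abs(r - R) <= 0.5, 1.0)


class TestClip:
    def test_no_outliers_unchanged(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 100.0])  # mu=20, sigma=40: 100 < 20+160
        assert np.array_equal(clip_outliers(x, 4.0), x)

    def test_extreme_value_clipped_to_bound(self):
        x = np.array([10.0] * 99 + [1e6])
        mu, sigma = x.mean(), x.std()
        out = clip_outliers(x, 4.0)
        assert out[-1] == pytest.approx(mu + 4 * sigma)
        assert np.array_equal(out[:-1], x[:-1])
        assert len(out) == len(x)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            clip_outliers(np.array([1.0]))


class TestNormalize:
    def test_three_point_example(self):
        assert np.allclose(normalize_intensity([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])

    def test_affine_invariance(self, rng):
        x = rng.random(50)
        assert np.allclose(normalize_intensity(x), normalize_intensity(3.2 * x + 17.0))

    def test_two_values_hit_bounds(self):
        assert np.allclose(normalize_intensity([3.0, 7.0]), [0.0, 1.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_intensity([4.0, 4.0])


class TestAverage:
    def test_two_extremes(self):
        assert average_normalized_intensity(np.array([0.0, 1.0])) == 0.5

    def test_constant_returns_value(self):
        assert average_normalized_intensity(np.full(10, 0.37)) == pytest.approx(0.37)

    def test_uniform_monte_carlo(self, rng):
        x = rng.random(100_000)
        assert average_normalized_intensity(x) == pytest.approx(0.5, abs=0.005)


class TestSkewness:
    def test_symmetric_distribution_zero(self):
        x = np.concatenate([np.linspace(0, 1, 101), 1 - np.linspace(0, 1, 101)])
        assert intensity_skewness(x) == pytest.approx(0.0, abs=1e-12)

    def test_three_element_brute_force(self):
        # {0, 0, 1}: mean 1/3, population sd sqrt(2)/3
        x = np.array([0.0, 0.0, 1.0])
        expected = (2 * (-1 / 3) ** 3 + (2 / 3) ** 3) / (3 * (math.sqrt(2) / 3) ** 3)
        assert intensity_skewness(x) == pytest.approx(expected)

    def test_reflection_antisymmetry(self, rng):
        x = rng.beta(2, 5, size=1000)
        assert intensity_skewness(1 - x) == pytest.approx(-intensity_skewness(x), rel=1e-9)

    def test_matches_scipy_population_convention(self, rng):
        from scipy import stats

        x = rng.random(500)
        assert intensity_skewness(x) == pytest.approx(float(stats.skew(x, bias=True)), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            intensity_skewness(np.full(5, 0.5))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 10_000))
    def test_streaming_equals_direct(self, seed, n):
        x = np.random.default_rng(seed).random(n)
        direct = intensity_skewness(x)
        stream = streaming_skewness(x, chunk=257)
        assert stream == pytest.approx(direct, rel=1e-10, abs=1e-10)


class TestCurvature:
    def test_sphere_mean_K_matches_inverse_radius_squared(self):
        vol, mask = spherical_field(49, 18.0)
        fld = curvature_field(vol, mask)
        assert np.mean(fld.K) * 18.0**2 == pytest.approx(1.0, rel=0.10)

    def test_kappa_product_and_ordering(self):
        vol, mask = spherical_field(41, 14.0)
        fld = curvature_field(vol, mask)
        assert np.allclose(fld.K, fld.kappa1 * fld.kappa2, rtol=1e-9)
        assert np.all(fld.kappa1 >= fld.kappa2)

    def test_flat_slab_zero_curvature(self):
        from scipy import ndimage

        n = 41
        vol = np.zeros((n, n, n))
        vol[n // 2] = 1.0
        vol = ndimage.gaussian_filter(vol, 2.0)
        mask = np.zeros((n, n, n), bool)
        mask[n // 2 - 1 : n // 2 + 2, 10:31, 10:31] = True
        fld = curvature_field(VoxelGrid3D(vol, (1.0, 1.0, 1.0)), LaminaMask(mask, 1.0))
        assert np.abs(fld.K).max() <= 1e-4

    def test_monkey_saddle_negative_K(self):
        """The monkey saddle z = x^3 - 3xy^2 has K = -36(x^2+y^2)/(1+|grad|^2)^2,
        strictly negative away from the origin."""
        from scipy import ndimage

        n = 49
        c = (n - 1) / 2
        z, y, x = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
        h = (x**3 - 3 * x * y**2) / 400.0
        vol = ndimage.gaussian_filter(1.0 / (1.0 + ((z - h) / 3.0) ** 2), 1.0)
        ring = (x**2 + y**2 >= 9) & (x**2 + y**2 <= 64)
        mask = (np.abs(z - h) <= 1.0) & ring
        fld = curvature_field(VoxelGrid3D(vol, (1.0, 1.0, 1.0)), LaminaMask(mask, 1.0))
        assert np.all(fld.K < 0)

    def test_physical_units_scale_with_spacing(self):
        vol, mask = spherical_field(41, 14.0)
        fld_1nm = curvature_field(vol, mask)
        vol60 = VoxelGrid3D(vol.values, (60.0, 60.0, 60.0))
        fld_60nm = curvature_field(vol60, LaminaMask(mask.values, 60.0))
        assert np.allclose(fld_60nm.K, fld_1nm.K / 60.0**2)

    def test_empty_mask_rejected(self):
        vol, _ = spherical_field(21, 6.0)
        with pytest.raises(ValueError):
            curvature_field(vol, LaminaMask(np.zeros(vol.shape, bool), 1.0))


class TestConvexHull:
    def test_cuboid_closed_form(self):
        """Hull of an a*b*c voxel cuboid spans (a-1)x(b-1)x(c-1) voxel centres."""
        mask = np.zeros((12, 14, 16), bool)
        mask[2:8, 3:10, 4:13] = True  # 6 x 7 x 9 voxels
        area = convex_hull_area(LaminaMask(mask, 60.0))
        a, b, c = 5, 6, 8  # centre-to-centre extents
        assert area == pytest.approx(2 * (a * b + b * c + c * a) * 60.0**2, rel=1e-9)

    def test_hull_ignores_internal_structure(self):
        full = np.zeros((10, 10, 10), bool)
        full[2:8, 2:8, 2:8] = True
        hollow = full.copy()
        hollow[3:7, 3:7, 3:7] = False
        assert convex_hull_area(LaminaMask(full, 60.0)) == pytest.approx(
            convex_hull_area(LaminaMask(hollow, 60.0))
        )

    def test_sphere_area(self):
        n = 45
        c = (n - 1) / 2
        z, y, x = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
        r = np.sqrt(z**2 + y**2 + x**2)
        R = 18.0
        mask = (r <= R) & (r >= R - 1.5)
        area = convex_hull_area(LaminaMask(mask, 1.0))
        assert area == pytest.approx(4 * math.pi * R**2, rel=0.03)

    def test_coplanar_mask_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2] = True
        with pytest.raises(ValueError, match="degenerate"):
            convex_hull_area(LaminaMask(mask, 60.0))


class TestNormalizedCurvature:
    def test_sphere_identity_4pi(self):
        """On an ideal sphere mean|K| = 1/R^2 and A_CH = 4 pi R^2, so the
        normalized curvature is 4 pi at any radius."""
        for R in (16.0, 20.0):
            vol, mask = spherical_field(2 * int(R) + 13, R)
            fld = curvature_field(vol, mask)
            k = normalized_curvature(fld, convex_hull_area(mask))
            assert k == pytest.approx(4 * math.pi, rel=0.10)

    def test_zero_field(self):
        vol, mask = spherical_field(41, 14.0)
        fld = curvature_field(vol, mask)
        fld.K[:] = 0.0
        assert normalized_curvature(fld, 1.0) == 0.0


class TestMeasureCell:
    def test_invaginated_phantom_has_larger_curvature(self, optics):
        base = l3.PhantomSpec(seed=31)
        dented = replace(
            base,
            invaginations=(
                l3.Invagination((0, 0.8, 0.6), 650.0, 500.0),
                l3.Invagination((0.3, -0.7, 0.6), 650.0, 500.0),
            ),
        )
        fv_smooth = l3.measure_cell(l3.image_phantom(l3.render_shell(base), base), optics)
        fv_dent = l3.measure_cell(l3.image_phantom(l3.render_shell(dented), dented), optics)
        assert fv_dent.K_naaGc > fv_smooth.K_naaGc

    def test_hotspots_raise_skewness(self, optics):
        base = l3.PhantomSpec(seed=32)
        spotted = replace(
            base,
            hotspots=(
                l3.Hotspot((0, 0.8, 0.6), 3.0, 0.35),
                l3.Hotspot((0.3, -0.7, 0.6), 2.5, 0.35),
            ),
        )
        fv_plain = l3.measure_cell(l3.image_phantom(l3.render_shell(base), base), optics)
        fv_spot = l3.measure_cell(l3.image_phantom(l3.render_shell(spotted), spotted), optics)
        assert abs(fv_spot.i_skewness) > abs(fv_plain.i_skewness)

    def test_deterministic(self, optics):
        spec = l3.PhantomSpec(seed=33)
        stack = l3.image_phantom(l3.render_shell(spec), spec)
        a = l3.measure_cell(stack, optics)
        b = l3.measure_cell(stack, optics)
        assert (a.i_average, a.i_skewness, a.K_naaGc) == (b.i_average, b.i_skewness, b.K_naaGc)
        assert 0 <= a.i_average <= 1
        assert a.A_CH > 0 and a.K_naaGc >= 0


class TestSpatialMaps:
    def test_uniform_shell_statistically_flat_intensity_map(self, rng):
        """A shell of uniform brightness (up to iid noise) projects to a map
        with no systematic structure: column means scatter around 1/2."""
        vol, mask = spherical_field(41, 14.0)
        fld = curvature_field(vol, mask)
        grid = VoxelGrid3D(
            np.where(mask.values, 5.0, 0.0) + rng.normal(0, 0.1, vol.shape), (1.0, 1.0, 1.0)
        )
        imap, _ = spatial_maps(grid, mask, fld, axis=0)
        vals = imap[~np.isnan(imap)]
        assert abs(vals.mean() - 0.5) < 0.05
        assert vals.std() < 0.25

    def test_hotspot_location_dominates_map(self, optics):
        spec = l3.PhantomSpec(
            semi_axes=(1000.0, 1000.0, 1000.0),
            spacing=(60.0, 60.0, 60.0),
            hotspots=(l3.Hotspot((0.0, 0.0, 1.0), 4.0, 0.3),),
            seed=4,
        )
        img = l3.image_phantom(l3.render_shell(spec), spec, noise=False)
        iso = l3.apply_lateral_blur(img, l3.blur_correction_sigma(62.0, 190.0))
        mask = l3.true_shell_mask(spec)
        fld = curvature_field(iso, mask)
        imap, _ = spatial_maps(iso, mask, fld, axis=0)
        _, xmax = np.unravel_index(np.nanargmax(imap), imap.shape)
        assert xmax > imap.shape[1] * 0.7  # hotspot sits on the +x rim

    def test_empty_mask_rejected(self):
        vol, mask = spherical_field(21, 6.0)
        fld = curvature_field(vol, mask)
        with pytest.raises(ValueError):
            spatial_maps(vol, LaminaMask(np.zeros(vol.shape, bool), 1.0), fld)


class TestIntensityCurvatureCorrelation:
    def test_perfect_proportionality(self):
        x = np.linspace(0.1, 1.0, 500)
        hist, rho = intensity_curvature_correlation(x, 3.5 * x)
        assert rho == pytest.approx(1.0)
        assert hist.sum() == 500

    def test_independent_fields_uncorrelated(self, rng):
        x, y = rng.random(100_000), rng.random(100_000)
        _, rho = intensity_curvature_correlation(x, y)
        assert abs(rho) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            intensity_curvature_correlation(np.full(10, 0.5), np.arange(10.0))
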