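"""Curvature measures: principal curvatures, shape index, curvedness,
category bands and the Butterworth shape-weight function."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafvein as lv
from leafvein.curvature import PLANAR_LABEL, SHAPE_CATEGORIES


def _field_from_height(z):
    gy, gx = np.gradient(z)
    ones = np.ones_like(z)
    return lv.GradientField(p=-gx, q=-gy, albedo=ones,
                            valid=np.ones_like(z, dtype=bool))


def _analytic_sphere_field(H=129, R=200.0):
    yy, xx = np.mgrid[0:H, 0:H].astype(float)
    c = (H - 1) / 2.0
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    z = np.sqrt(np.clip(R**2 - r2, 1.0, None))
    zx = -(xx - c) / z
    zy = -(yy - c) / z
    return lv.GradientField(p=-zx, q=-zy, albedo=np.ones_like(z),
                            valid=np.ones_like(z, bool)), r2, c


class TestPrincipalCurvatures:
    def test_plane_has_zero_curvature(self):
        z = 0.3 * np.arange(64)[None, :] + 0.1 * np.arange(64)[:, None]
        k1, k2 = lv.principal_curvatures(_field_from_height(z.astype(float)))
        interior = np.s_[8:-8, 8:-8]
        assert np.allclose(k1[interior], 0.0, atol=1e-10)
        assert np.allclose(k2[interior], 0.0, atol=1e-10)

    def test_hemisphere_curvatures_match_radius(self):
        R = 200.0
        field, r2, c = _analytic_sphere_field(R=R)
        k1, k2 = lv.principal_curvatures(field, sigma_px=2.0)
        inner = r2 <= (0.5 * c) ** 2  # inner 50% of the cap
        assert np.abs(k1[inner] * R - 1).max() < 0.05
        assert np.abs(k2[inner] * R - 1).max() < 0.05

    def test_concave_parabolic_cylinder(self):
        # z = +a x^2 / 2 recedes from the camera away from the axis: a rut
        a = 0.01
        H = W = 101
        xx = np.mgrid[0:H, 0:W][1].astype(float) - (W - 1) / 2
        z = a * xx**2 / 2.0
        k1, k2 = lv.principal_curvatures(_field_from_height(z), sigma_px=2.0)
        band = (np.abs(xx) < 20)
        band[:10] = band[-10:] = False
        # closed form at offset x: k = -a / (1 + (a x)^2)^(3/2)
        k_exact = -a / (1.0 + (a * xx) ** 2) ** 1.5
        assert np.abs(k2[band] / k_exact[band] - 1).max() < 0.05
        assert np.abs(k1[band]).max() < 0.05 * a

    def test_convex_cylinder_has_positive_curvature(self):
        a = 0.01
        xx = np.mgrid[0:101, 0:101][1].astype(float) - 50
        z = -a * xx**2 / 2.0  # bulges toward the camera
        k1, k2 = lv.principal_curvatures(_field_from_height(z), sigma_px=2.0)
        band = np.abs(xx) < 20
        assert np.median(k1[band]) == pytest.approx(a, rel=0.05)

    def test_ordering_k1_ge_k2(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((64, 64))
        from scipy import ndimage
        z = ndimage.gaussian_filter(z, 4.0)
        k1, k2 = lv.principal_curvatures(_field_from_height(z))
        assert np.all(k1 >= k2 - 1e-15)

    def test_non_positive_sigma_rejected(self):
        field = _field_from_height(np.zeros((16, 16)))
        with pytest.raises(ValueError, match="sigma"):
            lv.principal_curvatures(field, sigma_px=0.0)


class TestShapeIndex:
    @pytest.mark.parametrize("k1, k2, expected", [
        (0.0, -2.0, -0.5),   # canonical rut
        (2.0, 0.0, +0.5),    # canonical ridge
        (1.5, 1.5, +1.0),    # convex umbilic: spherical cap
        (-1.5, -1.5, -1.0),  # concave umbilic: spherical cup
    ])
    def test_canonical_shapes(self, k1, k2, expected):
        s = lv.shape_index(np.array([k1]), np.array([k2]))
        assert s[0] == pytest.approx(expected, abs=1e-12)

    def test_range_is_closed_unit_interval(self):
        rng = np.random.default_rng(1)
        k2 = rng.normal(size=1000)
        k1 = k2 + np.abs(rng.normal(size=1000))
        s = lv.shape_index(k1, k2)
        assert np.all(s >= -1.0) and np.all(s <= 1.0)

    def test_wrong_order_rejected(self):
        with pytest.raises(ValueError, match="k1 >= k2"):
            lv.shape_index(np.array([0.0]), np.array([1.0]))

    def test_scale_invariance_of_shape_decoupled_from_curvedness(self):
        # scaling heights scales curvedness linearly but leaves s fixed
        a = 0.002  # small-slope regime
        xx = np.mgrid[0:101, 0:101][1].astype(float) - 50
        for t in (1.0, 3.0):
            z = -t * a * xx**2 / 2.0
            k1, k2 = lv.principal_curvatures(_field_from_height(z),
                                             sigma_px=2.0)
            band = np.abs(xx) < 15
            s = lv.shape_index(k1, k2)
            c = lv.curvedness(k1, k2)
            assert np.median(s[band]) == pytest.approx(0.5, abs=0.02)
            assert np.median(c[band]) == pytest.approx(
                t * a / np.sqrt(2), rel=0.05)


class TestClassifyShape:
    @pytest.mark.parametrize("s, name", [
        (-1.0, "spherical cup"),
        (-0.5, "rut"),
        (-0.375, "saddle rut"),   # boundary excluded from rut (half-open)
        (0.0, "saddle"),
        (0.5, "ridge"),
        (1.0, "spherical cap"),
    ])
    def test_band_membership(self, s, name):
        label = lv.classify_shape(np.array([s]))[0]
        assert SHAPE_CATEGORIES[label] == name

    def test_planar_pixels_labelled_separately(self):
        labels = lv.classify_shape(np.array([0.5, np.nan]),
                                   planar=np.array([False, True]))
        assert labels[1] == PLANAR_LABEL


class TestCurvedness:
    def test_planar_gives_zero(self):
        assert lv.curvedness(np.zeros(3), np.zeros(3)).max() == 0.0

    def test_direct_evaluation(self):
        c = lv.curvedness(np.array([4.0]), np.array([3.0]))
        assert c[0] == pytest.approx(np.sqrt(12.5))

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        c = lv.curvedness(rng.normal(size=100), rng.normal(size=100))
        assert np.all(c >= 0)


class TestShapeWeight:
    def test_unit_weight_at_band_centre(self):
        for pol, sm in (("rut", -0.5), ("ridge", 0.5)):
            w = lv.shape_weight_map(np.array([sm]), pol).weights
            assert w[0] == 1.0

    def test_half_power_at_cutoff(self):
        w = lv.shape_weight_map(np.array([-0.1]), "rut",
                                sigma=4.0, omega=0.4).weights
        assert w[0] == pytest.approx(0.5, abs=1e-12)

    def test_rut_weights_zero_on_convex_shapes(self):
        s = np.array([0.3, 0.0, 1.0])
        w = lv.shape_weight_map(s, "rut").weights
        assert np.all(w == 0.0)

    def test_ridge_weights_zero_on_concave_shapes(self):
        s = np.array([-0.3, 0.0, -1.0])
        w = lv.shape_weight_map(s, "ridge").weights
        assert np.all(w == 0.0)

    def test_flat_pass_band_over_rut_category(self):
        s = np.linspace(-0.625, -0.375, 100, endpoint=False)
        w = lv.shape_weight_map(s, "rut").weights
        assert w.min() > 0.999

    def test_disjoint_supports(self):
        s = np.linspace(-1, 1, 401)
        wr = lv.shape_weight_map(s, "ridge").weights
        wu = lv.shape_weight_map(s, "rut").weights
        assert np.all(wr * wu == 0.0)

    def test_planar_pixels_get_zero_weight(self):
        w = lv.shape_weight_map(np.array([-0.5]), "rut",
                                planar=np.array([True])).weights
        assert w[0] == 0.0

    def test_non_positive_cutoff_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            lv.shape_weight_map(np.array([0.5]), "ridge", omega=0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-0.99, -0.01), st.floats(-0.99, -0.01))
    def test_symmetric_and_monotone_about_centre(self, s_a, s_b):
        """Weight depends only on |s - s_m| and decreases away from it."""
        w = lv.shape_weight_map(np.array([s_a, s_b, -1.0 - s_a]),
                                "rut").weights
        # mirror image about s_m = -0.5 has identical weight
        assert w[0] == pytest.approx(w[2], rel=1e-12)
        if abs(s_a + 0.5) <= abs(s_b + 0.5):
            assert w[0] >= w[1]


class TestCurvatureMaps:
    def test_from_gradients_on_sphere(self):
        field, r2, c = _analytic_sphere_field()
        maps = lv.CurvatureMaps.from_gradients(field, sigma_px=2.0)
        inner = r2 <= (0.5 * c) ** 2
        assert np.nanmedian(maps.s[inner]) > 0.99  # spherical cap
        assert np.all(maps.c >= 0)
        assert np.all(maps.k1 >= maps.k2)

    def test_planarity_mask_on_flat_surface(self):
        z = np.zeros((32, 32))
        maps = lv.CurvatureMaps.from_gradients(_field_from_height(z))
        assert maps.planar.all()
        assert np.all(np.isnan(maps.s))
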