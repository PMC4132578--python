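import numpy as np
import pytest

from foveal_attention import SaliencyWeights, SkinModel, combine_saliency, saliency_map
from foveal_attention.color import ColorValue
from foveal_attention.saliency import (
    DegenerateRegionError,
    color_contrast,
    intensity_contrast,
    mask_moments,
    moments_and_roundness,
    normalize_features,
    orientation_contrast,
    proximity,
    skin_score,
    symmetry,
)

from test_segmentation import make_proto


def disc_mask(r, size=64):
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - size / 2) ** 2 + (yy - size / 2) ** 2 <= r * r


def bar_mask(length=50, thickness=1, angle=0.0, size=80):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - size / 2, yy - size / 2
    t = np.deg2rad(angle)
    u = np.cos(t) * dx + np.sin(t) * dy
    v = -np.sin(t) * dx + np.cos(t) * dy
    return (np.abs(u) <= length / 2) & (np.abs(v) <= thickness / 2)


class TestContrasts:
    def test_matching_neighbors_zero(self):
        e = [50.0, 0.0, 120.0]
        i = make_proto(0, 10, e, None, 10, {1: (10, 0)})
        j = make_proto(1, 10, e, None, 10, {0: (10, 0)})
        assert color_contrast(i, {1: j}) == 0.0
        assert intensity_contrast(i, {1: j}) == 0.0

    def test_gray_object_suppressed(self):
        # S_i = 0 -> ColCON = 0 regardless of neighbors
        i = make_proto(0, 10, [0.0, 0.0, 0.0], None, 10, {1: (10, 0)})
        j = make_proto(1, 10, [255.0, 0.0, 255.0], None, 10, {0: (10, 0)})
        assert color_contrast(i, {1: j}) == 0.0
        assert intensity_contrast(i, {1: j}) == 255.0

    def test_single_neighbor_hand_value(self):
        # S_i = 0.5, full shared boundary, d = 100 -> ColCON = 50
        i = make_proto(0, 10, [127.5, 0.0, 0.0], None, 40, {1: (40, 0)})
        j = make_proto(1, 10, [127.5, 0.0, 100.0], None, 40, {0: (40, 0)})
        assert color_contrast(i, {1: j}) == pytest.approx(50.0)

    def test_intensity_two_neighbors_weighted(self):
        # halves of the boundary at |ΔI| = 40 and 80 -> 60
        i = make_proto(0, 10, [0, 0, 100.0], None, 20, {1: (10, 0), 2: (10, 0)})
        j = make_proto(1, 10, [0, 0, 140.0], None, 10, {})
        k = make_proto(2, 10, [0, 0, 180.0], None, 10, {})
        assert intensity_contrast(i, {1: j, 2: k}) == pytest.approx(60.0)

    def test_full_boundary_single_neighbor(self):
        i = make_proto(0, 10, [0, 0, 0.0], None, 12, {1: (12, 0)})
        j = make_proto(1, 10, [0, 0, 80.0], None, 12, {0: (12, 0)})
        assert intensity_contrast(i, {1: j}) == pytest.approx(80.0)

    def test_degenerate_region_raises(self):
        i = make_proto(0, 10, [0, 0, 0], None, 0, {})
        with pytest.raises(DegenerateRegionError):
            color_contrast(i, {})


class TestProximity:
    @pytest.mark.parametrize("depth,expected", [(2.0, 0.5), (1.0, 1.0), (4.0, 0.25)])
    def test_inverse_depth(self, depth, expected):
        p = make_proto(0, 10, [0, 0, 0], depth, 10, {})
        assert proximity(p) == pytest.approx(expected)

    def test_disparity_passthrough(self):
        p = make_proto(0, 10, [0, 0, 0], 7.5, 10, {})
        assert proximity(p, depth_is_disparity=True) == 7.5

    def test_missing_or_invalid_depth(self):
        assert proximity(make_proto(0, 1, [0, 0, 0], None, 1, {})) is None
        assert proximity(make_proto(0, 1, [0, 0, 0], -1.0, 1, {})) is None


class TestMomentsAndShape:
    def test_disc_is_round(self):
        _, round_ = moments_and_roundness(disc_mask(20))
        assert round_ >= 0.99

    def test_thin_bar_has_zero_roundness(self):
        mask = np.zeros((60, 60), bool)
        mask[30, 5:55] = True  # 1×50 horizontal bar
        ms, round_ = moments_and_roundness(mask)
        assert ms.eccentricity == pytest.approx(1.0)
        assert round_ == pytest.approx(0.0)

    def test_ellipse_closed_form(self):
        # semi-axes 40/20: ecc = ((4−1)/(4+1))² = 0.36 -> ROUND = 0.64
        yy, xx = np.mgrid[0:120, 0:120].astype(float)
        mask = ((xx - 60) / 40) ** 2 + ((yy - 60) / 20) ** 2 <= 1.0
        _, round_ = moments_and_roundness(mask)
        assert round_ == pytest.approx(0.64, abs=0.02)

    def test_single_pixel_defined_round(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        ms, round_ = moments_and_roundness(mask)
        assert round_ == 1.0 and ms.orientation == 0.0

    def test_bar_orientation(self):
        assert mask_moments(bar_mask(angle=0)).orientation == pytest.approx(0.0, abs=0.5)
        # image y grows downward: a shape drawn at +30° in array coords
        # reports −30° in the mathematical convention
        phi = mask_moments(bar_mask(angle=30)).orientation
        assert abs(abs(phi) - 30.0) <= 1.0

    def test_disc_orientation_isotropic_convention(self):
        assert mask_moments(disc_mask(15)).orientation == pytest.approx(0.0, abs=1e-6)


class TestOrientationContrast:
    def test_no_contrast_when_aligned(self):
        assert orientation_contrast(10.0, [10.0, 10.0]) == 0.0

    def test_orthogonal_neighbor(self):
        assert orientation_contrast(0.0, [90.0]) == pytest.approx(90.0)

    def test_hand_sum(self):
        assert orientation_contrast(0.0, [10.0, 20.0, 30.0]) == pytest.approx(60.0)

    def test_axial_wrapping(self):
        assert orientation_contrast(-80.0, [80.0]) == pytest.approx(20.0)


class TestSymmetry:
    def test_disc_fully_symmetric(self):
        assert symmetry(disc_mask(15), 0.0) >= 0.98

    def test_single_axis_shape_uses_max_not_mean(self):
        # isoceles-triangle-ish mask: mirror-symmetric about the vertical axis
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        mask = (yy >= 10) & (yy <= 30) & (np.abs(xx - 20) <= (yy - 8) / 2)
        scores = [symmetry(mask, phi) for phi in (0.0,)]
        s = symmetry(mask, 0.0)
        assert s >= 0.9  # the best axis dominates even if others are poor

    def test_uneven_l_less_symmetric_than_its_symmetrization(self):
        # an equal-armed L is mirror-symmetric about its 45° diagonal, so use
        # unequal arms to obtain a genuinely asymmetric polyomino
        mask = np.zeros((48, 48), bool)
        mask[10:40, 10:16] = True  # long vertical arm
        mask[34:40, 10:26] = True  # short horizontal arm
        sym_union = mask | mask[:, ::-1]
        assert symmetry(mask, 0.0) < symmetry(sym_union, 0.0)

    def test_rotation_invariance_with_axes(self):
        m0 = bar_mask(length=30, thickness=9, angle=0)
        m45 = bar_mask(length=30, thickness=9, angle=45)
        s0 = symmetry(m0, mask_moments(m0).orientation)
        s45 = symmetry(m45, mask_moments(m45).orientation)
        assert s0 == pytest.approx(s45, abs=0.08)


class TestSkin:
    def test_model_mean_is_skin(self):
        model = SkinModel()
        skin_rgb_hsv = ColorValue(27.0, 0.53, 0.88)  # a canonical skin tone
        assert skin_score(skin_rgb_hsv, model) == 255.0

    def test_threshold_inclusive_and_blue_rejected(self):
        model = SkinModel()
        blue = ColorValue(240.0, 1.0, 1.0)
        assert model.mahalanobis(blue) > model.theta
        assert skin_score(blue, model) == 0.0
        boundary = SkinModel(theta=model.mahalanobis(blue))
        assert skin_score(blue, boundary) == 255.0

    def test_covariance_validated(self):
        with pytest.raises(ValueError):
            SkinModel(cov=((1.0, 2.0), (2.0, 1.0)))  # not positive definite


class TestNormalizationAndCombination:
    def test_single_object_maps_to_255(self):
        raw = np.array([[3.0, 0.0, 1.0, 0.5, 10.0, 0.2, 255.0]])
        norm = normalize_features(raw)
        assert set(np.unique(norm)) <= {0.0, 255.0}
        assert norm[0, 0] == 255.0 and norm[0, 1] == 0.0

    def test_two_objects_scaled(self):
        raw = np.zeros((2, 7))
        raw[:, 0] = [10.0, 20.0]
        norm = normalize_features(raw)
        assert norm[0, 0] == pytest.approx(127.5)
        assert norm[1, 0] == pytest.approx(255.0)

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 50, size=(6, 7))
        norm = normalize_features(raw)
        for k in range(7):
            assert (np.argsort(norm[:, k]) == np.argsort(raw[:, k])).all()

    def test_combine_selects_single_feature(self):
        w = SaliencyWeights((1, 0, 0, 0, 0, 0, 0))
        f = np.array([[70.0, 1, 2, 3, 4, 5, 6]])
        assert combine_saliency(f, w)[0] == 70.0

    def test_convexity_constant_features(self):
        w = SaliencyWeights((0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2))
        f = np.full((1, 7), 42.0)
        assert combine_saliency(f, w)[0] == pytest.approx(42.0)

    def test_hand_dot_product(self):
        w = SaliencyWeights((1 / 7,) * 7)
        f = np.array([[70.0, 140.0, 0.0, 210.0, 0.0, 0.0, 0.0]])
        assert combine_saliency(f, w)[0] == pytest.approx(60.0)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            SaliencyWeights((1, 1, 0, 0, 0, 0, 0))
        w = SaliencyWeights((2, 0, 0, 0, 0, 0, 0), auto_renormalize=True)
        assert w.as_array()[0] == 1.0

    def test_missing_prox_renormalizes(self):
        w = SaliencyWeights((1 / 7,) * 7)
        f = np.array([[60.0, 60.0, np.nan, 60.0, 60.0, 60.0, 60.0]])
        assert combine_saliency(f, w)[0] == pytest.approx(60.0)


class TestSaliencyMap:
    def test_constant_for_single_object(self):
        labels = np.zeros((8, 8), int)
        out = saliency_map(labels, np.array([42.0]))
        assert (out == 42.0).all()

    def test_pixelwise_lookup(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=(10, 10))
        sal = rng.uniform(0, 255, 4)
        out = saliency_map(labels, sal)
        assert set(np.unique(out)) <= set(sal)
        for k in range(4):
            assert (out[labels == k] == sal[k]).all()
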