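"""Gradient, thresholding, contour tracing, the classical chain, deep path."""

import numpy as np
import pytest

from cappheno.edge_pipeline import (
    DeepPathUnavailableError,
    DegenerateHistogramError,
    EdgeChainConfig,
    classical_edge_chain,
    deep_backbone_forward,
    filter_small_contours,
    find_contours,
    init_backbone_weights,
    rasterize_contours,
    sobel_gradient_magnitude,
    threshold_edge_map,
)
from cappheno.synthetic_caps import BACKGROUND_COLORS, SyntheticCapSpec, gen_cap_image

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def brute_force_sobel(img):
    img = np.asarray(img, dtype=float)
    padded = np.pad(img, 1, mode="symmetric")
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + 3, j : j + 3]
            gx[i, j] = (win * _SOBEL_X).sum()
            gy[i, j] = (win * _SOBEL_X.T).sum()
    return np.hypot(gx, gy)


class TestSobel:
    def test_constant_is_zero(self):
        assert (sobel_gradient_magnitude(np.full((6, 6), 9.0)) == 0).all()

    def test_vertical_step_peak(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 7.0
        grad = sobel_gradient_magnitude(img)
        assert grad[4, 3] == pytest.approx(4 * 7.0)
        assert grad[4, 4] == pytest.approx(4 * 7.0)
        assert grad[4, 1] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 255, (8, 8))
        assert np.abs(sobel_gradient_magnitude(img) - brute_force_sobel(img)).max() < 1e-9

    def test_rotation_covariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (16, 16))
        g = sobel_gradient_magnitude(img)
        g_rot = sobel_gradient_magnitude(np.rot90(img))
        assert np.abs(np.rot90(g) - g_rot).max() <= 0.05 * g.max()


class TestThreshold:
    def test_fixed(self):
        grad = np.array([[3.0, 7.0]])
        np.testing.assert_array_equal(
            threshold_edge_map(grad, "fixed", 5.0), [[False, True]]
        )

    def test_otsu_clean_bimodal(self):
        # hand Otsu on a 2-level histogram: any threshold between the modes
        # maximises between-class variance, so exactly the 200s survive
        rng = np.random.default_rng(0)
        grad = np.where(rng.random((20, 20)) < 0.4, 200.0, 10.0)
        edges = threshold_edge_map(grad, "otsu")
        np.testing.assert_array_equal(edges, grad == 200.0)

    def test_strict_inequality_at_zero(self):
        assert not threshold_edge_map(np.zeros((4, 4)), "fixed", 0.0).any()

    def test_constant_map_degenerate_for_otsu(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_edge_map(np.full((5, 5), 3.0), "otsu")


class TestFindContours:
    def test_filled_square_single_contour_36_pixels(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        contours = find_contours(m)
        assert len(contours) == 1
        assert contours[0].hierarchy_level == "outer"
        assert len(contours[0]) == 36
        # deterministic start: topmost-then-leftmost boundary pixel
        assert tuple(contours[0].points[0]) == (5, 5)

    def test_two_disjoint_blobs(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:6, 2:6] = True
        m[10:18, 10:18] = True
        contours = find_contours(m)
        assert len(contours) == 2
        # descending area ordering
        assert contours[0].area_px >= contours[1].area_px

    def test_ring_has_outer_and_inner(self):
        yy, xx = np.mgrid[:40, :40]
        d2 = (yy - 20) ** 2 + (xx - 20) ** 2
        ring = (d2 <= 144) & (d2 >= 49)
        levels = [c.hierarchy_level for c in find_contours(ring)]
        assert levels == ["outer", "inner"]

    def test_empty_raster_empty_list(self):
        assert find_contours(np.zeros((5, 5), dtype=bool)) == []

    def test_chain_is_closed_and_adjacent(self):
        yy, xx = np.mgrid[:60, :60]
        blob = (yy - 30) ** 2 + (xx - 30) ** 2 <= 400
        pts = find_contours(blob)[0].points
        steps = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0)).max(axis=1)
        assert (steps <= 1).all()


class TestFilterSmallContours:
    def test_filtering(self):
        m = np.zeros((40, 60), dtype=bool)
        m[2:6, 2:6] = True  # shoelace area 9
        m[10:30, 10:40] = True  # shoelace area 551
        contours = find_contours(m)
        kept, count = filter_small_contours(contours, min_area=50.0)
        assert count == 1 and kept[0].area_px > 500

    def test_zero_threshold_keeps_all(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:5, 2:5] = True
        m[10:14, 10:14] = True
        contours = find_contours(m)
        kept, count = filter_small_contours(contours, 0.0)
        assert count == len(contours)

    def test_threshold_above_everything(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:8, 2:8] = True
        _, count = filter_small_contours(find_contours(m), 1e6)
        assert count == 0

    def test_kept_areas_respect_threshold_fuzzed(self):
        rng = np.random.default_rng(3)
        m = rng.random((48, 48)) < 0.35
        contours = find_contours(m)
        kept, _ = filter_small_contours(contours, 4.0)
        assert all(c.area_px >= 4.0 for c in kept)


class TestClassicalChain:
    def test_clean_cap_single_surviving_contour(self, clean_cap):
        result = classical_edge_chain(clean_cap.image)
        assert result.count == 1

    def test_suppression_never_increases_contour_count(self, noisy_cap):
        on = classical_edge_chain(noisy_cap.image)
        off = classical_edge_chain(noisy_cap.image, EdgeChainConfig(suppress=False))
        assert on.count <= off.count

    def test_background_only_image_count_zero(self):
        img = np.full((64, 64, 3), BACKGROUND_COLORS["green"], dtype=np.uint8)
        result = classical_edge_chain(img)
        assert result.count == 0 and not result.edge_map.any()

    def test_edge_map_is_rasterized_contours(self, clean_cap):
        result = classical_edge_chain(clean_cap.image)
        np.testing.assert_array_equal(
            result.edge_map, rasterize_contours(result.contours, result.edge_map.shape)
        )


@pytest.fixture(scope="module")
def small_cap():
    return gen_cap_image(
        SyntheticCapSpec(
            image_height=64,
            image_width=64,
            center=(32.0, 32.0),
            semi_long=14.0,
            semi_short=10.0,
            seed=0,
        )
    )


class TestDeepBackbone:

    def test_shape_and_range(self, small_cap):
        out = deep_backbone_forward(small_cap.image, init_backbone_weights(0, width=4))
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_zero_weights_give_half(self, small_cap):
        w = {k: np.zeros_like(v) for k, v in init_backbone_weights(0, width=4).items()}
        assert np.allclose(deep_backbone_forward(small_cap.image, w), 0.5)

    def test_missing_weights_explicit_error(self, small_cap):
        with pytest.raises(DeepPathUnavailableError):
            deep_backbone_forward(small_cap.image, None)
        with pytest.raises(DeepPathUnavailableError):
            deep_backbone_forward(small_cap.image, {"block1/conv1/w": np.zeros((4, 4, 3, 3))})
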