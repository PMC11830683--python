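"""Trait morphometry: areas, perimeters, rectangles, axes, colours, calibration."""

import math

import numpy as np
import pytest

from cappheno.edge_pipeline import find_contours
from cappheno.phenotype import (
    CalibrationFactor,
    CapPhenotype,
    DegenerateContourError,
    calibrate,
    color_means,
    contour_area,
    contour_perimeter,
    equivalent_ellipse_axes,
    extract_phenotype,
    min_area_rect,
    roundness,
)
from cappheno.synthetic_caps import SyntheticCapSpec, gen_cap_image


def disk_mask(r, pad=10):
    size = 2 * (r + pad)
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


class TestContourArea:
    def test_square(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]])
        assert contour_area(sq) == pytest.approx(100.0)

    def test_triangle(self):
        assert contour_area(np.array([[0, 0], [4, 0], [0, 3]])) == pytest.approx(6.0)

    @pytest.mark.parametrize("r", [30, 50])
    def test_rasterized_circle_within_2pct(self, r):
        c = find_contours(disk_mask(r))[0]
        assert contour_area(c) == pytest.approx(math.pi * r * r, rel=0.02)

    def test_degenerate(self):
        with pytest.raises(DegenerateContourError):
            contour_area(np.array([[0, 0], [1, 1]]))


class TestContourPerimeter:
    def test_square(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]])
        assert contour_perimeter(sq) == pytest.approx(40.0)

    def test_out_and_back_two_points(self):
        assert contour_perimeter(np.array([[0, 0], [3, 4]])) == pytest.approx(10.0)

    @pytest.mark.parametrize("r", [30, 50])
    def test_rasterized_circle_within_3pct(self, r):
        c = find_contours(disk_mask(r))[0]
        assert contour_perimeter(c) == pytest.approx(2 * math.pi * r, rel=0.03)

    def test_single_point_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert contour_perimeter(np.array([[5, 5]])) == 0.0

    def test_uncorrected_is_plain_segment_sum(self):
        chain = np.array([[0, 0], [1, 0], [2, 1], [2, 2]])
        expected = 1.0 + math.sqrt(2) + 1.0 + math.hypot(2, 2)
        assert contour_perimeter(chain, corrected=False) == pytest.approx(expected)


class TestMinAreaRect:
    def test_axis_aligned_box(self):
        box = np.array([[0, 0], [30, 0], [30, 10], [0, 10]], dtype=float)
        length, width, angle = min_area_rect(box)
        assert (length, width) == pytest.approx((30.0, 10.0))
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_rotated_box_recovered_within_1pct(self):
        box = np.array([[0, 0], [30, 0], [30, 10], [0, 10]], dtype=float)
        th = math.radians(17)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        length, width, angle = min_area_rect(box @ rot.T)
        assert length == pytest.approx(30.0, rel=0.01)
        assert width == pytest.approx(10.0, rel=0.01)
        assert angle == pytest.approx(17.0, abs=0.5)

    def test_circle_square_box_within_2pct(self):
        c = find_contours(disk_mask(50))[0]
        length, width, _ = min_area_rect(c)
        assert length == pytest.approx(100.0, rel=0.02)
        assert width == pytest.approx(100.0, rel=0.02)

    def test_collinear_degenerate(self):
        with pytest.raises(DegenerateContourError):
            min_area_rect(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float))


class TestRoundness:
    @pytest.mark.parametrize("lw,expected", [((10, 10), 1.0), ((20, 10), 0.5), ((30.0, 24.3), 0.81)])
    def test_values(self, lw, expected):
        assert roundness(*lw) == pytest.approx(expected)

    def test_width_exceeding_length_rejected(self):
        with pytest.raises(ValueError):
            roundness(10, 20)


class TestEquivalentEllipseAxes:
    def test_disk(self):
        long_ax, short_ax, _ = equivalent_ellipse_axes(disk_mask(50))
        assert long_ax == pytest.approx(100.0, rel=0.02)
        assert short_ax == pytest.approx(100.0, rel=0.02)

    def test_ellipse(self):
        yy, xx = np.mgrid[:200, :200]
        m = ((xx - 100) / 60.0) ** 2 + ((yy - 100) / 40.0) ** 2 <= 1
        long_ax, short_ax, orient = equivalent_ellipse_axes(m)
        assert long_ax == pytest.approx(120.0, rel=0.02)
        assert short_ax == pytest.approx(80.0, rel=0.02)
        assert orient == pytest.approx(0.0, abs=1.0)

    def test_single_pixel_degenerate_warning(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        with pytest.warns(UserWarning):
            assert equivalent_ellipse_axes(m)[:2] == (0.0, 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            equivalent_ellipse_axes(np.zeros((5, 5), dtype=bool))


class TestColorMeans:
    def test_uniform_region(self):
        img = np.full((6, 6, 3), (10, 20, 30), dtype=np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        r, g, b, grey = color_means(img, mask)
        assert (r, g, b) == (10.0, 20.0, 30.0)
        assert grey == pytest.approx(0.299 * 10 + 0.587 * 20 + 0.114 * 30)

    def test_single_pixel(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[1, 2] = (9, 8, 7)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        assert color_means(img, mask)[:3] == (9.0, 8.0, 7.0)

    def test_black_white_symmetry(self):
        img = np.zeros((2, 4, 3), dtype=np.uint8)
        img[:, 2:] = 255
        r, g, b, grey = color_means(img, np.ones((2, 4), dtype=bool))
        assert (r, g, b) == (127.5, 127.5, 127.5)
        assert grey == pytest.approx(127.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_means(np.zeros((3, 3, 3), dtype=np.uint8), np.zeros((3, 3), dtype=bool))


def _phen_px(**kw):
    defaults = dict(
        ext_rect_length=1000.0,
        ext_rect_width=800.0,
        roundness=0.8,
        area=10000.0,
        perimeter=3000.0,
        long_axis=1000.0,
        short_axis=800.0,
        red_mean=100.0,
        green_mean=90.0,
        blue_mean=80.0,
        greyscale_mean=92.0,
        centroid=(50.0, 50.0),
        units="px",
    )
    defaults.update(kw)
    return CapPhenotype(**defaults)


class TestCalibrate:
    def test_default_factor_converts_lengths(self):
        p = calibrate(_phen_px(), CalibrationFactor())
        assert p.ext_rect_length == pytest.approx(43.0)  # 1000 px at 0.043 mm/px
        assert p.units == "mm"

    def test_identity_factor(self):
        p = calibrate(_phen_px(), CalibrationFactor(1.0))
        assert p.area == 10000.0 and p.perimeter == 3000.0

    def test_area_scales_squared(self):
        p = calibrate(_phen_px(), CalibrationFactor(0.043))
        assert p.area == pytest.approx(10000 * 0.043**2)
        assert p.roundness == 0.8 and p.red_mean == 100.0


@pytest.fixture(scope="module")
def big_cap():
    # large, eccentric, orientation away from the digitisation-ambiguous
    # band where the min-area rectangle of the raster legitimately
    # deviates from the oriented 2a x 2b box
    return gen_cap_image(
        SyntheticCapSpec(
            image_height=512,
            image_width=512,
            center=(256.0, 256.0),
            semi_long=140.0,
            semi_short=95.0,
            orientation=35.0,
            seed=2,
        )
    )


class TestExtractPhenotype:

    def test_scale_traits_match_analytic_truth(self, big_cap):
        p = extract_phenotype(big_cap.image, big_cap.mask, CalibrationFactor(1.0))
        truth = big_cap.phenotype
        for trait in (
            "area",
            "perimeter",
            "long_axis",
            "short_axis",
            "ext_rect_length",
            "ext_rect_width",
        ):
            assert getattr(p, trait) == pytest.approx(getattr(truth, trait), rel=0.03), trait

    def test_colour_means_exact_on_noise_free_cap(self, big_cap):
        p = extract_phenotype(big_cap.image, big_cap.mask, CalibrationFactor(1.0))
        truth = big_cap.phenotype
        assert p.red_mean == pytest.approx(truth.red_mean, abs=0.5)
        assert p.greyscale_mean == pytest.approx(truth.greyscale_mean, abs=0.5)

    def test_disk_roundness_near_one(self):
        mask = disk_mask(60)
        img = np.full((*mask.shape, 3), (150, 100, 60), dtype=np.uint8)
        p = extract_phenotype(img, mask, CalibrationFactor(1.0))
        assert p.roundness == pytest.approx(1.0, abs=0.02)

    def test_roundness_always_in_unit_interval(self, big_cap):
        p = extract_phenotype(big_cap.image, big_cap.mask)
        assert 0.0 < p.roundness <= 1.0

    def test_scale_equivariance(self):
        small = gen_cap_image(
            SyntheticCapSpec(
                image_height=256,
                image_width=256,
                center=(128.0, 128.0),
                semi_long=60.0,
                semi_short=45.0,
                orientation=0.0,
                seed=3,
            )
        )
        big = gen_cap_image(
            SyntheticCapSpec(
                image_height=512,
                image_width=512,
                center=(256.0, 256.0),
                semi_long=120.0,
                semi_short=90.0,
                orientation=0.0,
                seed=3,
            )
        )
        f = CalibrationFactor(1.0)
        ps = extract_phenotype(small.image, small.mask, f)
        pb = extract_phenotype(big.image, big.mask, f)
        assert pb.area == pytest.approx(4 * ps.area, rel=0.03)
        assert pb.perimeter == pytest.approx(2 * ps.perimeter, rel=0.03)

    def test_rotation_invariance_of_scale_traits(self):
        base = dict(
            image_height=512,
            image_width=512,
            center=(256.0, 256.0),
            semi_long=140.0,
            semi_short=95.0,
            seed=4,
        )
        a = gen_cap_image(SyntheticCapSpec(orientation=35.0, **base))
        b = gen_cap_image(SyntheticCapSpec(orientation=65.0, **base))
        f = CalibrationFactor(1.0)
        pa = extract_phenotype(a.image, a.mask, f)
        pb = extract_phenotype(b.image, b.mask, f)
        for trait in ("area", "perimeter", "long_axis", "short_axis", "roundness"):
            assert getattr(pa, trait) == pytest.approx(getattr(pb, trait), rel=0.02), trait

    def test_weight_window_warning(self):
        with pytest.warns(UserWarning):
            _phen_px(weight=300.0)
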