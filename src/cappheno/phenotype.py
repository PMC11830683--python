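"""Cap trait measurement: the 11 morphometric and colour traits.

Traits are measured from a cap mask and its outer contour: external
rectangle (minimum-area rotated enclosing rectangle via rotating calipers),
roundness (bounded width/length ratio of that rectangle), area and
perimeter (shoelace / arc length of the contour polygon), long and short
axes (moment-equivalent ellipse of the mask), per-channel colour means and
the greyscale mean over the mask, plus the mask centroid.  Pixel
measurements are converted to millimetres with a scalar calibration factor
(lengths x f, areas x f^2); the rig's derived factor, 0.043 mm/px, is the
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .edge_pipeline import Contour, find_contours
from .reference import DEFAULT_MM_PER_PX, TRAIT_NAMES, WEIGHT_COLUMN

__all__ = [
    "CapPhenotype",
    "CalibrationFactor",
    "DegenerateContourError",
    "contour_area",
    "contour_perimeter",
    "min_area_rect",
    "roundness",
    "equivalent_ellipse_axes",
    "color_means",
    "calibrate",
    "extract_phenotype",
]


class DegenerateContourError(ValueError):
    """Contour has too few (or collinear) points for the requested trait."""


@dataclass
class CalibrationFactor:
    """Millimetres represented by one pixel."""

    mm_per_px: float = DEFAULT_MM_PER_PX

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class CapPhenotype:
    """One cap's trait record.

    Scale traits are in the units named by ``units`` ("px" or "mm"; area in
    the squared unit).  ``weight`` is an optional measured weight in grams.
    """

    ext_rect_length: float
    ext_rect_width: float
    roundness: float
    area: float
    perimeter: float
    long_axis: float
    short_axis: float
    red_mean: float
    green_mean: float
    blue_mean: float
    greyscale_mean: float
    centroid: tuple[float, float]
    orientation_deg: float = 0.0
    weight: float | None = None
    units: str = "px"
    pixel: "CapPhenotype | None" = None

    def __post_init__(self) -> None:
        if self.weight is not None and not (50.0 <= self.weight <= 200.0):
            warnings.warn(
                f"weight {self.weight:.1f} g outside the 50-200 g window of the "
                "calibration standard",
                stacklevel=2,
            )

    def to_row(self) -> dict[str, float]:
        """Trait record as a dict keyed by the canonical trait column names."""
        values = (
            self.ext_rect_length,
            self.ext_rect_width,
            self.roundness,
            self.area,
            self.perimeter,
            self.long_axis,
            self.short_axis,
            self.red_mean,
            self.green_mean,
            self.blue_mean,
            self.greyscale_mean,
        )
        row = dict(zip(TRAIT_NAMES, values))
        if self.weight is not None:
            row[WEIGHT_COLUMN] = self.weight
        return row


def _contour_points(c: "Contour | np.ndarray") -> np.ndarray:
    pts = c.points if isinstance(c, Contour) else c
    return np.asarray(pts, dtype=float)


def contour_area(c: "Contour | np.ndarray", corrected: bool = True) -> float:
    """Area of the closed contour polygon (shoelace), in px^2.

    For pixel-chain contours (every segment a unit or diagonal lattice
    step) the shoelace polygon threads pixel centres and understates the
    enclosed pixel region by half the boundary; with ``corrected`` (default)
    the exact lattice-polygon relation (Pick's theorem) adds B/2 + 1 so the
    value matches the pixel count of the region.  Ordinary polygons are
    measured by the plain shoelace formula either way.
    """
    pts = _contour_points(c)
    if len(pts) < 3:
        raise DegenerateContourError("area needs at least 3 contour points")
    x, y = pts[:, 0], pts[:, 1]
    area = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
    if corrected:
        diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        seg = np.hypot(diffs[:, 0], diffs[:, 1])
        if (seg <= math.sqrt(2.0) + 1e-9).all():
            area += len(pts) / 2.0 + 1.0
    return area


# Kulpa's estimator: a digitised smooth boundary's chain length overstates
# the true arc length by ~5%; scaling lattice steps by pi(1+sqrt(2))/8
# removes the bias (raw chain length of a digitised circle is ~+5%).
_KULPA = math.pi * (1.0 + math.sqrt(2.0)) / 8.0


def contour_perimeter(c: "Contour | np.ndarray", corrected: bool = True) -> float:
    """Closed polygon arc length: Euclidean segment sum including closure.

    With ``corrected`` (default), unit and diagonal lattice steps — the
    segments a pixel-chain contour is made of — are scaled by Kulpa's
    factor so digitised smooth boundaries are measured without the ~5%
    chain-length bias; longer segments (true polygon edges) are untouched.
    """
    pts = _contour_points(c)
    if len(pts) < 2:
        warnings.warn("single-point contour has zero perimeter", stacklevel=2)
        return 0.0
    diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    seg = np.hypot(diffs[:, 0], diffs[:, 1])
    if corrected:
        lattice = (np.abs(seg - 1.0) < 1e-9) | (np.abs(seg - math.sqrt(2.0)) < 1e-9)
        seg = np.where(lattice, seg * _KULPA, seg)
    return float(seg.sum())


def min_area_rect(c: "Contour | np.ndarray") -> tuple[float, float, float]:
    """Minimum-area enclosing rotated rectangle (rotating calipers).

    Returns (length, width, angle_deg) with length >= width; the angle is
    the direction of the length side in degrees within [-90, 90).
    """
    pts = _contour_points(c)
    if len(pts) < 3:
        raise DegenerateContourError("rectangle needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateContourError("collinear contour points") from exc
    hp = pts[hull.vertices]
    best = None
    n = len(hp)
    for i in range(n):
        edge = hp[(i + 1) % n] - hp[i]
        theta = math.atan2(edge[1], edge[0])
        cos_t, sin_t = math.cos(-theta), math.sin(-theta)
        rot = hp @ np.array([[cos_t, -sin_t], [sin_t, cos_t]]).T
        dx = rot[:, 0].max() - rot[:, 0].min()
        dy = rot[:, 1].max() - rot[:, 1].min()
        area = dx * dy
        if best is None or area < best[0]:
            best = (area, dx, dy, theta)
    _, dx, dy, theta = best
    if dx >= dy:
        length, width, angle = dx, dy, math.degrees(theta)
    else:
        length, width, angle = dy, dx, math.degrees(theta) + 90.0
    angle = (angle + 90.0) % 180.0 - 90.0
    return float(length), float(width), float(angle)


def roundness(length: float, width: float) -> float:
    """Bounded width/length ratio of the external rectangle, in (0, 1]."""
    if width <= 0 or length <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        raise ValueError("width must not exceed length")
    return width / length


def equivalent_ellipse_axes(mask: np.ndarray) -> tuple[float, float, float]:
    """Axes of the ellipse with the mask's second central moments.

    Returns (long_axis, short_axis, orientation_deg): axis lengths are
    4 * sqrt(eigenvalue) of the pixel-coordinate covariance, so a filled
    disk of radius r yields both axes ~= 2r.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    if len(xs) == 1:
        warnings.warn("single-pixel mask is degenerate", stacklevel=2)
        return 0.0, 0.0, 0.0
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = float((x * x).mean())
    mu02 = float((y * y).mean())
    mu11 = float((x * y).mean())
    common = math.hypot(mu20 - mu02, 2 * mu11)
    lam1 = (mu20 + mu02 + common) / 2.0
    lam2 = (mu20 + mu02 - common) / 2.0
    orientation = math.degrees(0.5 * math.atan2(2 * mu11, mu20 - mu02))
    return 4.0 * math.sqrt(max(lam1, 0.0)), 4.0 * math.sqrt(max(lam2, 0.0)), orientation


def color_means(img: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """(R, G, B, grey) means over masked pixels; grey is the BT.601
    luminance of the channel means (== mean of the per-pixel luminance)."""
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    sel = img[mask].astype(float)
    r, g, b = sel[:, 0].mean(), sel[:, 1].mean(), sel[:, 2].mean()
    grey = 0.299 * r + 0.587 * g + 0.114 * b
    return float(r), float(g), float(b), float(grey)


def calibrate(p: CapPhenotype, f: CalibrationFactor) -> CapPhenotype:
    """Convert a pixel-unit phenotype to millimetres: lengths x f, area x
    f^2; colour means and roundness are unit-free and unchanged."""
    k = f.mm_per_px
    return replace(
        p,
        ext_rect_length=p.ext_rect_length * k,
        ext_rect_width=p.ext_rect_width * k,
        area=p.area * k * k,
        perimeter=p.perimeter * k,
        long_axis=p.long_axis * k,
        short_axis=p.short_axis * k,
        units="mm",
        pixel=p,
    )


def extract_phenotype(
    img: np.ndarray,
    mask: np.ndarray,
    f: CalibrationFactor | None = None,
) -> CapPhenotype:
    """Measure all 11 traits of a cap from its image and mask.

    Returns the calibrated (mm) phenotype; the raw pixel-unit record stays
    available as ``.pixel``.
    """
    f = f or CalibrationFactor()
    mask = np.asarray(mask).astype(bool)
    contours = find_contours(mask)
    outer = [c for c in contours if c.hierarchy_level == "outer"]
    if not outer or len(outer[0]) < 3:
        raise DegenerateContourError("mask has no 3-point outer contour")
    contour = outer[0]

    area = contour_area(contour)
    perim = contour_perimeter(contour)
    length, width, _ = min_area_rect(contour)
    long_ax, short_ax, orient = equivalent_ellipse_axes(mask)
    r, g, b, grey = color_means(img, mask)
    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()), float(ys.mean()))

    px = CapPhenotype(
        ext_rect_length=length,
        ext_rect_width=width,
        roundness=roundness(length, width),
        area=area,
        perimeter=perim,
        long_axis=long_ax,
        short_axis=short_ax,
        red_mean=r,
        green_mean=g,
        blue_mean=b,
        greyscale_mean=grey,
        centroid=centroid,
        orientation_deg=orient,
        units="px",
    )
    return calibrate(px, f)
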