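"""Edge extraction for cap images.

The classical chain realises the cap-edge procedure end to end: grayscale
conversion, Gaussian blur, Sobel gradient magnitude, LBP-based texture
suppression, thresholding (Otsu by default), ordered contour tracing, and
elimination of small-area contours.  The surviving outer contours are
rasterised into the final one-pixel-wide edge map and counted.

A reduced-scale six-block convolutional backbone (DexiNed-style topology
with a cluster-mask channel ahead of the first two blocks and texture
suppression on block-2 features) is provided as an optional forward-only
deep path; it requires an explicit weight bag and never silently replaces
the classical chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .preprocess import gaussian_blur, kd_kmeans, segment_cap, to_grayscale
from .texture import (
    DEFAULT_CLOSING_SIZE,
    DEFAULT_QUANTIZE,
    DEFAULT_SIGMA_S,
    DEFAULT_TAU,
    DEFAULT_WINDOW,
    lbp8,
    semi_gaussian_suppress,
    texture_prepare,
    texture_score,
)

__all__ = [
    "Contour",
    "EdgeChainConfig",
    "EdgeChainResult",
    "DegenerateHistogramError",
    "DeepPathUnavailableError",
    "sobel_gradient_magnitude",
    "threshold_edge_map",
    "find_contours",
    "filter_small_contours",
    "rasterize_contours",
    "classical_edge_chain",
    "init_backbone_weights",
    "deep_backbone_forward",
]

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


class DegenerateHistogramError(ValueError):
    """Otsu thresholding on a constant gradient map."""


class DeepPathUnavailableError(RuntimeError):
    """The deep backbone was requested without a usable weight bag."""


@dataclass
class Contour:
    """Closed, ordered pixel-chain boundary of one region.

    points : (N, 2) int array of (x, y) pixel coordinates, ordered along the
        boundary; first and last points are 8-adjacent.
    area_px : shoelace area of the pixel-centre polygon.
    hierarchy_level : ``"outer"`` or ``"inner"`` (hole boundary).
    """

    points: np.ndarray
    area_px: float
    hierarchy_level: str = "outer"

    def __len__(self) -> int:
        return len(self.points)


def sobel_gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) with 3x3 Sobel kernels,
    reflective border handling."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    gx = ndimage.correlate(img, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


def threshold_edge_map(
    grad: np.ndarray, method: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Binarise a gradient map; pixel true iff magnitude > threshold.

    ``otsu`` computes the threshold on a 256-bin histogram of magnitudes
    normalised to [0, 1]; ``fixed`` uses ``value`` on the raw scale.
    """
    grad = np.asarray(grad, dtype=float)
    if (grad < 0).any():
        raise ValueError("gradient magnitudes must be non-negative")
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        return grad > value
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    lo, hi = float(grad.min()), float(grad.max())
    if hi == lo:
        raise DegenerateHistogramError("constant gradient map has no Otsu threshold")
    norm = (grad - lo) / (hi - lo)
    t = threshold_otsu(norm, nbins=256)
    return norm > t


# ---------------------------------------------------------------------------
# Contour tracing (Moore boundary following, 8-connected)
# ---------------------------------------------------------------------------

# clockwise directions starting north, as (dy, dx)
_DIRS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_CONN8 = np.ones((3, 3), dtype=bool)


def shoelace_area(points: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon given as (x, y) vertices."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore boundary trace of a single 8-connected region.

    Starts at the topmost-then-leftmost pixel and walks clockwise, keeping
    the backtrack (background) position alongside the current pixel; stops
    by Jacob's criterion: re-entering the start pixel with the original
    backtrack.  Returns (N, 2) points as (x, y); thin sections are visited
    out and back, so the chain is always a closed cycle.
    """
    rows, cols = np.nonzero(mask)
    r0 = int(rows.min())
    c0 = int(cols[rows == r0].min())
    start = (r0, c0)
    h, w = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and bool(mask[p])

    path = [start]
    cur = start
    back = (r0 - 1, c0)  # pixel above the start is background by construction
    first_state = None
    for _ in range(4 * int(mask.sum()) + 8):
        db = _DIR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        found = False
        for step in range(1, 9):
            d = (db + step) % 8
            nb = (cur[0] + _DIRS[d][0], cur[1] + _DIRS[d][1])
            if fg(nb):
                prev = (d - 1) % 8
                back = (cur[0] + _DIRS[prev][0], cur[1] + _DIRS[prev][1])
                cur = nb
                found = True
                break
        if not found:  # isolated pixel
            return np.array([(start[1], start[0])])
        # the cycle is complete when the state reached by the first move recurs
        if first_state is None:
            first_state = (cur, back)
        elif (cur, back) == first_state:
            break
        path.append(cur)
    if len(path) > 1 and path[-1] == path[0]:
        path.pop()
    return np.array([(p[1], p[0]) for p in path])


def _trace_component(mask: np.ndarray) -> np.ndarray:
    pts = _trace_boundary(mask)
    # drop the duplicated closing run: keep unique ordered cycle
    if len(pts) > 1 and (pts[0] == pts[-1]).all():
        pts = pts[:-1]
    return pts


def find_contours(binary: np.ndarray) -> list[Contour]:
    """Ordered closed boundaries of all 8-connected regions, with hierarchy.

    Outer contours are sorted by descending shoelace area; each is followed
    by the boundaries of its interior holes (``hierarchy_level="inner"``).
    An empty raster yields an empty list.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2:
        raise ValueError("expected a 2-D binary raster")
    if not binary.any():
        return []
    labels, n = ndimage.label(binary, structure=_CONN8)
    outers: list[tuple[Contour, list[Contour]]] = []
    for i in range(1, n + 1):
        comp = labels == i
        pts = _trace_component(comp)
        outer = Contour(points=pts, area_px=shoelace_area(pts), hierarchy_level="outer")
        inners: list[Contour] = []
        filled = ndimage.binary_fill_holes(comp)
        holes = filled & ~comp
        if holes.any():
            hlabels, hn = ndimage.label(holes, structure=_CONN8)
            for j in range(1, hn + 1):
                hpts = _trace_component(hlabels == j)
                inners.append(
                    Contour(points=hpts, area_px=shoelace_area(hpts), hierarchy_level="inner")
                )
        outers.append((outer, inners))
    outers.sort(key=lambda t: -t[0].area_px)
    result: list[Contour] = []
    for outer, inners in outers:
        result.append(outer)
        result.extend(sorted(inners, key=lambda c: -c.area_px))
    return result


def filter_small_contours(
    contours: list[Contour], min_area: float
) -> tuple[list[Contour], int]:
    """Keep contours whose area is >= ``min_area``; return (kept, count)."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    kept = [c for c in contours if c.area_px >= min_area]
    return kept, len(kept)


def rasterize_contours(contours: list[Contour], shape: tuple[int, int]) -> np.ndarray:
    """Paint contour pixel chains into a boolean edge map of ``shape``."""
    out = np.zeros(shape, dtype=bool)
    for c in contours:
        pts = np.asarray(c.points)
        out[pts[:, 1], pts[:, 0]] = True
    return out


# ---------------------------------------------------------------------------
# Classical chain
# ---------------------------------------------------------------------------


@dataclass
class EdgeChainConfig:
    """Tunables of the classical edge chain."""

    sigma: float = 1.0
    ksize: int = 5
    suppress: bool = True
    tau: float = DEFAULT_TAU
    sigma_s: float = DEFAULT_SIGMA_S
    window: int = DEFAULT_WINDOW
    closing_size: int = DEFAULT_CLOSING_SIZE
    quantize: float = DEFAULT_QUANTIZE
    method: str = "otsu"
    value: float | None = None
    #: minimum surviving contour area in px^2 at 512x512; scales with image
    #: area.  Set well above residual texture blobs (a few hundred px^2) and
    #: well below any plausible cap (tens of thousands of px^2).
    min_area: float = 400.0
    debug: bool = False


@dataclass
class EdgeChainResult:
    edge_map: np.ndarray
    contours: list[Contour]
    count: int
    #: confidence-valued edge map: surviving edge pixels carry a score in
    #: [0.2, 1] ranking them by (suppressed) gradient support, zero
    #: elsewhere; this is what threshold-sweeping evaluation consumes
    edge_confidence: np.ndarray | None = None
    debug: dict = field(default_factory=dict)


def effective_min_area(min_area: float, shape: tuple[int, int]) -> float:
    """Scale the 512x512-referenced area threshold to the actual frame."""
    return min_area * (shape[0] * shape[1]) / (512.0 * 512.0)


def classical_edge_chain(img: np.ndarray, cfg: EdgeChainConfig | None = None) -> EdgeChainResult:
    """Run the full classical edge procedure on a colour image.

    Stages: grayscale -> Gaussian blur -> Sobel gradient -> LBP/half-Gaussian
    texture suppression -> threshold -> contour tracing -> small-area
    elimination.  The returned edge map is the rasterisation of the surviving
    outer contours; ``count`` is their number.  A frame with no gradient
    contrast at all yields an empty map and count 0.
    """
    cfg = cfg or EdgeChainConfig()
    gray = to_grayscale(img)
    blurred = gaussian_blur(gray, cfg.sigma, cfg.ksize)
    grad = sobel_gradient_magnitude(blurred)
    debug: dict = {}
    if cfg.debug:
        debug["gray"] = gray
        debug["grad_raw"] = grad.copy()
    if cfg.suppress:
        prepared = texture_prepare(gray, cfg.closing_size, cfg.quantize)
        score = texture_score(lbp8(prepared), cfg.window)
        grad = semi_gaussian_suppress(grad, score, cfg.tau, cfg.sigma_s)
        if cfg.debug:
            debug["texture_score"] = score
            debug["grad_suppressed"] = grad
    try:
        edges = threshold_edge_map(grad, cfg.method, cfg.value)
    except DegenerateHistogramError:
        edges = np.zeros(grad.shape, dtype=bool)
    contours = find_contours(edges)
    outer = [c for c in contours if c.hierarchy_level == "outer"]
    kept, count = filter_small_contours(outer, effective_min_area(cfg.min_area, edges.shape))
    edge_map = rasterize_contours(kept, edges.shape)
    gmax = float(grad.max())
    confidence = np.where(edge_map, 0.2 + 0.8 * grad / gmax, 0.0) if gmax > 0 else edge_map.astype(float)
    if cfg.debug:
        debug["thresholded"] = edges
    return EdgeChainResult(
        edge_map=edge_map, contours=kept, count=count, edge_confidence=confidence, debug=debug
    )


# ---------------------------------------------------------------------------
# Optional reduced-scale deep backbone (forward only)
# ---------------------------------------------------------------------------

_BLOCK_WIDTHS = (1, 2, 4, 4, 4, 4)  # multiples of the base width


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 (or 1x1) same-padding convolution; x is (C, H, W), w is
    (C_out, C_in, kh, kw)."""
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (C_in, H, W, kh, kw)
    out = np.einsum("chwij,ocij->ohw", win, w, optimize=True)
    return out + b[:, None, None]


def _pool2(x: np.ndarray) -> np.ndarray:
    """2x2 mean pooling with edge padding to even size; x is (C, H, W)."""
    c, h, w = x.shape
    if h % 2 or w % 2:
        x = np.pad(x, ((0, 0), (0, h % 2), (0, w % 2)), mode="edge")
        c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _upsample_to(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsample a 2-D map to ``shape``."""
    zy = shape[0] / x.shape[0]
    zx = shape[1] / x.shape[1]
    out = ndimage.zoom(x, (zy, zx), order=1, grid_mode=True, mode="nearest")
    return out[: shape[0], : shape[1]]


def init_backbone_weights(seed: int = 0, width: int = 8) -> dict[str, np.ndarray]:
    """He-normal random weight bag for the reduced six-block backbone."""
    rng = np.random.default_rng(seed)
    bag: dict[str, np.ndarray] = {"__width__": np.array([width])}

    def he(shape: tuple[int, ...]) -> np.ndarray:
        fan_in = int(np.prod(shape[1:]))
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    c_prev = 4  # RGB + cluster-mask channel
    for b, mult in enumerate(_BLOCK_WIDTHS, start=1):
        c_out = width * mult
        c_in = c_prev + (1 if b == 2 else 0)  # mask re-concatenated at block 2
        bag[f"block{b}/conv1/w"] = he((c_out, c_in, 3, 3))
        bag[f"block{b}/conv1/b"] = np.zeros(c_out)
        bag[f"block{b}/conv2/w"] = he((c_out, c_out, 3, 3))
        bag[f"block{b}/conv2/b"] = np.zeros(c_out)
        bag[f"side{b}/w"] = he((1, c_out, 1, 1))
        bag[f"side{b}/b"] = np.zeros(1)
        c_prev = c_out
    return bag


def deep_backbone_forward(
    img: np.ndarray, weights: dict[str, np.ndarray] | None
) -> np.ndarray:
    """Forward pass of the reduced six-block edge backbone.

    The KD-Kmeans cap/background assignment is concatenated as an extra
    input channel ahead of blocks 1 and 2, and the half-Gaussian texture
    suppression weight is applied to block-2 features before its side
    output.  Per-block side outputs are upsampled to the input size, fused
    by averaging, and passed through a sigmoid, giving an edge-probability
    map in [0, 1].
    """
    if weights is None:
        raise DeepPathUnavailableError(
            "deep path unavailable: no weight bag supplied "
            "(use init_backbone_weights or train externally)"
        )
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 colour image")
    required = {f"block{b}/conv{i}/w" for b in range(1, 7) for i in (1, 2)}
    missing = required - set(weights)
    if missing:
        raise DeepPathUnavailableError(f"deep path unavailable: missing weights {sorted(missing)[:3]}")

    h, w = img.shape[:2]
    x_rgb = img.astype(float).transpose(2, 0, 1) / 255.0
    try:
        model = kd_kmeans(img, k=2)
        mask = segment_cap(img, model).astype(float)
    except Exception:
        mask = np.zeros((h, w))
    gray = to_grayscale(img)
    score = texture_score(lbp8(texture_prepare(gray)), DEFAULT_WINDOW)
    supp_weight = np.exp(-(np.maximum(score - DEFAULT_TAU, 0.0) ** 2) / (2 * DEFAULT_SIGMA_S**2))

    sides = []
    x = np.concatenate([x_rgb, mask[None]], axis=0)
    cur_mask = mask
    cur_supp = supp_weight
    for b in range(1, 7):
        if b >= 2:
            x = _pool2(x)
            cur_mask = _pool2(cur_mask[None])[0]
            cur_supp = _pool2(cur_supp[None])[0]
        if b == 2:
            x = np.concatenate([x, cur_mask[None]], axis=0)
        x = np.maximum(_conv2d(x, weights[f"block{b}/conv1/w"], weights[f"block{b}/conv1/b"]), 0.0)
        x = np.maximum(_conv2d(x, weights[f"block{b}/conv2/w"], weights[f"block{b}/conv2/b"]), 0.0)
        if b == 2:
            x = x * cur_supp[None]
        side = _conv2d(x, weights[f"side{b}/w"], weights[f"side{b}/b"])[0]
        sides.append(_upsample_to(side, (h, w)))
    fused = np.mean(sides, axis=0)
    return 1.0 / (1.0 + np.exp(-fused))
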