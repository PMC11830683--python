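"""Cap/background separation: grayscale, Gaussian blur, KD-seeded K-means.

The segmentation front end treats every frame as one cap on a uniform
coloured background.  Pixels are clustered in RGB space with K-means whose
initial centres come from the leaves of a KD-tree built over the pixel
colours ("KD-Kmeans"): leaf mean colours are candidate centres and a greedy
farthest-point sweep picks the k of them that are maximally spread.  With
k=2 the background cluster is identified as the one owning the majority of
image-border pixels; the other cluster, reduced to its largest connected
component with holes filled, is the cap mask.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ClusterModel",
    "SegmentationError",
    "AmbiguousBackgroundError",
    "EmptySegmentationError",
    "to_grayscale",
    "gaussian_blur",
    "gaussian_kernel",
    "build_kdtree_leaves",
    "kd_kmeans",
    "segment_cap",
    "segment_image",
]

# BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])

_KDTREE_LEAF_SIZE = 32
_LLOYD_MAX_ITER = 100


class SegmentationError(RuntimeError):
    """Base class for cap-segmentation failures."""


class AmbiguousBackgroundError(SegmentationError):
    """Both clusters own equally many image-border pixels."""


class EmptySegmentationError(SegmentationError):
    """The putative foreground cluster contains no pixels."""


@dataclass
class ClusterModel:
    """Fitted colour-clustering state.

    Attributes
    ----------
    k : number of clusters.
    centers : (k, 3) float array of cluster centre colours.
    assignment : (H, W) int array of per-pixel labels (ties -> lowest label).
    inertia : sum of squared pixel-to-centre distances.
    """

    k: int
    centers: np.ndarray
    assignment: np.ndarray
    inertia: float


def _validate_color_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 colour image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B, rounded half-up to ints."""
    img = _validate_color_image(img)
    lum = img.astype(float) @ _LUMA
    return np.floor(lum + 0.5).astype(np.int64)


def luminance(img: np.ndarray) -> np.ndarray:
    """Unrounded BT.601 luminance (float), used for mean-intensity traits."""
    return _validate_color_image(img).astype(float) @ _LUMA


def gaussian_kernel(sigma: float, ksize: int) -> np.ndarray:
    """Normalised 2-D Gaussian kernel of odd side ``ksize``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if ksize % 2 == 0 or ksize < 1:
        raise ValueError("ksize must be odd and positive")
    r = ksize // 2
    x = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_blur(img: np.ndarray, sigma: float, ksize: int) -> np.ndarray:
    """Convolve a grayscale image with a normalised Gaussian, reflective borders."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("gaussian_blur expects a 2-D grayscale image")
    kernel = gaussian_kernel(sigma, ksize)
    # symmetric kernel: correlation == convolution
    return ndimage.correlate(img, kernel, mode="reflect")


# ---------------------------------------------------------------------------
# KD-Kmeans
# ---------------------------------------------------------------------------


def build_kdtree_leaves(points: np.ndarray, leaf_size: int = _KDTREE_LEAF_SIZE) -> list[np.ndarray]:
    """Median-split KD-tree over colour points; returns the mean of each leaf.

    Splits cycle through dimensions; a node with <= ``leaf_size`` points is a
    leaf.  Leaves are returned in deterministic left-to-right order.
    """
    points = np.asarray(points, dtype=float)
    leaves: list[np.ndarray] = []

    def recurse(idx: np.ndarray, depth: int) -> None:
        if idx.size <= leaf_size:
            leaves.append(points[idx].mean(axis=0))
            return
        dim = depth % points.shape[1]
        order = np.argsort(points[idx, dim], kind="stable")
        idx = idx[order]
        mid = idx.size // 2
        recurse(idx[:mid], depth + 1)
        recurse(idx[mid:], depth + 1)

    recurse(np.arange(len(points)), 0)
    return leaves


def _farthest_point_selection(candidates: np.ndarray, k: int) -> np.ndarray:
    """Greedily pick k candidates maximising the minimum pairwise distance.

    The sweep starts from the candidate farthest from the candidate mean so
    the choice is deterministic.
    """
    mean = candidates.mean(axis=0)
    d0 = np.linalg.norm(candidates - mean, axis=1)
    chosen = [int(np.argmax(d0))]
    min_dist = np.linalg.norm(candidates - candidates[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(candidates - candidates[nxt], axis=1))
    return candidates[chosen]


def _assign(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # squared distances; argmin breaks ties toward the lowest label
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    return labels, d2


def kd_kmeans(pixels: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """K-means over colour triples seeded from KD-tree leaves.

    Parameters
    ----------
    pixels : (N, 3) array or (H, W, 3) image; clustering runs on the flat
        colour list, and for image input the assignment is reshaped to H x W.
    k : number of clusters; must not exceed the number of distinct colours.
    seed : kept for interface stability; the procedure is deterministic
        (median splits, farthest-point seeding, lowest-label ties).
    """
    arr = np.asarray(pixels, dtype=float)
    image_shape = None
    if arr.ndim == 3 and arr.shape[2] == 3:
        image_shape = arr.shape[:2]
        arr = arr.reshape(-1, 3)
    if arr.ndim != 2:
        raise ValueError("pixels must be (N, 3) or (H, W, 3)")
    n_distinct = len(np.unique(arr, axis=0))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct colours present")

    if len(arr) <= 16 and math.comb(len(arr), k) <= 256:
        # tiny inputs: KD leaves degenerate to one leaf, and a single Lloyd
        # run often sticks in a local optimum; restart from every k-subset
        # of the points and keep the lowest-inertia solution
        best = None
        for combo in itertools.combinations(range(len(arr)), k):
            centers, labels, inertia = _lloyd(arr, arr[list(combo)].copy(), k)
            if best is None or inertia < best[2] - 1e-12:
                best = (centers, labels, inertia)
        centers, labels, inertia = best
    else:
        leaves = np.asarray(build_kdtree_leaves(arr))
        if len(leaves) >= k:
            centers = _farthest_point_selection(leaves, k)
        else:
            # fewer leaves than clusters: top up with farthest raw points
            centers = _farthest_point_selection(np.vstack([leaves, arr]), k)
        centers, labels, inertia = _lloyd(arr, centers, k)

    if image_shape is not None:
        labels = labels.reshape(image_shape)
    return ClusterModel(k=k, centers=centers, assignment=labels, inertia=inertia)


def _lloyd(arr: np.ndarray, centers: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations to convergence (no label changes) or the cap."""
    labels = np.full(len(arr), -1)
    for _ in range(_LLOYD_MAX_ITER):
        new_labels, d2 = _assign(arr, centers)
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centers[j] = arr[sel].mean(axis=0)
            else:  # empty cluster: reseed with the farthest point overall
                centers[j] = arr[np.argmax(d2[np.arange(len(arr)), new_labels])]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    labels, d2 = _assign(arr, centers)
    inertia = float(d2[np.arange(len(arr)), labels].sum())
    return centers, labels, inertia


# ---------------------------------------------------------------------------
# Mask extraction
# ---------------------------------------------------------------------------

_CONN8 = np.ones((3, 3), dtype=bool)


def segment_cap(img: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Turn a fitted k=2 cluster model into a boolean cap mask.

    The cluster owning the majority of image-border pixels is background; the
    other cluster is reduced to its largest 8-connected component and its
    holes are filled.
    """
    img = _validate_color_image(img)
    if model.k != 2:
        raise ValueError("segment_cap requires a k=2 cluster model")
    labels = model.assignment
    if labels.shape != img.shape[:2]:
        raise ValueError("cluster assignment shape does not match image")

    border = np.concatenate([labels[0, :], labels[-1, :], labels[1:-1, 0], labels[1:-1, -1]])
    n1 = int((border == 1).sum())
    n0 = border.size - n1
    if n0 == n1:
        raise AmbiguousBackgroundError("border pixels split evenly between clusters")
    background = 0 if n0 > n1 else 1
    fg = labels == (1 - background)
    if not fg.any():
        raise EmptySegmentationError("foreground cluster is empty")

    comp, n_comp = ndimage.label(fg, structure=_CONN8)
    if n_comp == 0:
        raise EmptySegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = comp == largest
    return ndimage.binary_fill_holes(mask)


def segment_image(img: np.ndarray, seed: int = 0) -> np.ndarray:
    """Fit KD-Kmeans with k=2 on an image and return the cap mask.

    A frame showing only the background colour has nothing to segment and
    raises :class:`EmptySegmentationError`.
    """
    img = _validate_color_image(img)
    try:
        model = kd_kmeans(img, k=2, seed=seed)
    except ValueError as exc:
        raise EmptySegmentationError(
            "image has fewer than two distinct colours - nothing to segment"
        ) from exc
    return segment_cap(img, model)
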