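"""LBP texture scoring and half-Gaussian suppression of surface pattern.

Dried cap surfaces carry radial crack lines whose gradient response rivals
the true cap boundary.  The suppression stage measures local texture density
with 8-neighbour local binary patterns and attenuates the gradient response
wherever that density exceeds a threshold tau:

    w(score) = 1                                  if score <= tau
             = exp(-(score - tau)^2 / (2 sigma_s^2))   otherwise

so smooth regions (and the cap boundary, which is an isolated step rather
than dense texture) pass through unchanged while densely textured interior
regions are rolled off smoothly.  The half-Gaussian weight is this package's
concrete definition of the suppression; it is identity below threshold,
monotone in the exceedance, and never amplifies.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "lbp8",
    "nonuniform_code_table",
    "texture_prepare",
    "texture_score",
    "semi_gaussian_suppress",
    "DEFAULT_TAU",
    "DEFAULT_SIGMA_S",
    "DEFAULT_WINDOW",
    "DEFAULT_CLOSING_SIZE",
    "DEFAULT_QUANTIZE",
]

# Suppression weight calibration.  The non-uniform-fraction score is bounded
# well below 1 in practice (pixels at local extrema always code uniform, so
# even ideal dense texture saturates near ~0.5), while on the bottom-hat
# prepared input smooth regions and clean step edges score exactly 0.  The
# threshold/width pair below is set from that separation: identity below a
# small guard band, strong roll-off across the observed crack-score range.
DEFAULT_TAU = 0.05
DEFAULT_SIGMA_S = 0.10
DEFAULT_WINDOW = 9
#: greyscale closing footprint for the bottom-hat texture input (px)
DEFAULT_CLOSING_SIZE = 9
#: intensity quantisation step for the LBP input; above the bottom-hat
#: amplitude of pixel noise (~4 sigma), below the crack darkening contrast
DEFAULT_QUANTIZE = 40.0

# 8 neighbours clockwise from top-left, as (dy, dx); bit b is neighbour b.
_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def lbp8(img: np.ndarray) -> np.ndarray:
    """8-neighbour, radius-1 local binary pattern codes.

    Bit b is set iff neighbour b (clockwise from the top-left) is >= the
    centre pixel.  Border pixels carry code 0 by convention.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("lbp8 requires a 2-D image of at least 3x3")
    codes = np.zeros(img.shape, dtype=np.int64)
    centre = img[1:-1, 1:-1]
    acc = np.zeros(centre.shape, dtype=np.int64)
    for b, (dy, dx) in enumerate(_NEIGHBOURS):
        nb = img[1 + dy : img.shape[0] - 1 + dy, 1 + dx : img.shape[1] - 1 + dx]
        acc |= (nb >= centre).astype(np.int64) << b
    codes[1:-1, 1:-1] = acc
    return codes


def _circular_transitions(code: int) -> int:
    bits = [(code >> b) & 1 for b in range(8)]
    return sum(bits[b] != bits[(b + 1) % 8] for b in range(8))


def nonuniform_code_table() -> np.ndarray:
    """Boolean lookup over 0..255: True where the code has > 2 circular 0/1
    transitions (the standard non-uniform pattern criterion)."""
    return np.array([_circular_transitions(c) > 2 for c in range(256)])


_NONUNIFORM = nonuniform_code_table()


def texture_prepare(
    gray: np.ndarray,
    closing_size: int = DEFAULT_CLOSING_SIZE,
    quantize: float = DEFAULT_QUANTIZE,
) -> np.ndarray:
    """Contrast-aware LBP input: quantised bottom-hat of the grayscale.

    Plain radius-1 LBP is threshold-free, so arbitrarily small pixel noise
    flips its bits and flat regions score as texture.  The bottom-hat
    transform (greyscale closing minus image) isolates dark structures
    thinner than the closing footprint — exactly the surface cracks — while
    clean step edges and smooth regions map to ~0; floor-quantising by a
    step above the noise bottom-hat amplitude then makes untextured regions
    exactly constant (hence LBP-uniform) and leaves cracks as multi-level
    speckle.
    """
    gray = np.asarray(gray, dtype=float)
    if quantize <= 0:
        raise ValueError("quantize must be positive")
    bh = ndimage.grey_closing(gray, size=(closing_size, closing_size)) - gray
    return np.floor(bh / quantize)


def texture_score(lbp: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Fraction of non-uniform LBP codes in an odd square window, in [0, 1]."""
    lbp = np.asarray(lbp)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    indicator = _NONUNIFORM[lbp].astype(float)
    return ndimage.uniform_filter(indicator, size=window, mode="reflect")


def semi_gaussian_suppress(
    response: np.ndarray,
    score: np.ndarray,
    tau: float = DEFAULT_TAU,
    sigma_s: float = DEFAULT_SIGMA_S,
) -> np.ndarray:
    """Attenuate a gradient response by the half-Gaussian texture weight."""
    response = np.asarray(response, dtype=float)
    score = np.asarray(score, dtype=float)
    if response.shape != score.shape:
        raise ValueError(
            f"response shape {response.shape} != score shape {score.shape}"
        )
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    exceed = np.maximum(score - tau, 0.0)
    weight = np.exp(-(exceed**2) / (2.0 * sigma_s**2))
    return response * weight
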