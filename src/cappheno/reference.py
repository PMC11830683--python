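"""Reference constants for shiitake-cap phenotyping.

Trait names, the published summary statistics of the Jingxiang 118 cap
measurement campaign (686 samples), the published feature-weight correlation
ranking, and the fixed M1-M4 input groups used for weight prediction.
"""

from __future__ import annotations

# The 11 cap traits, in canonical column order; "Weight" (grams) is appended
# as the 12th column of a measurement table.
TRAIT_NAMES: tuple[str, ...] = (
    "External rectangular length",
    "External rectangular width",
    "Roundness",
    "Area",
    "Perimeter",
    "Long axis",
    "Short axis",
    "Red mean",
    "Green mean",
    "Blue mean",
    "Greyscale mean",
)

WEIGHT_COLUMN = "Weight"

#: Published per-trait summary of the 686-sample Jingxiang 118 measurement
#: table: (average, maximum, minimum, standard deviation, printed standard
#: score of the maximum, printed standard score of the minimum).
TRAIT_SUMMARY: dict[str, tuple[float, float, float, float, float, float]] = {
    "External rectangular length": (60.1, 69.24, 52.86, 4.65, 1.98, -1.55),
    "External rectangular width": (60.02, 66.86, 53.57, 3.89, 1.76, -1.66),
    "Roundness": (0.81, 0.9, 0.57, 0.069, 1.34, -3.38),
    "Area": (208.32, 244.58, 182.93, 16.54, 2.19, -1.54),
    "Perimeter": (2782.4, 3351.2, 2215.15, 343.02, 1.66, -1.65),
    "Long axis": (39.75, 43.15, 32.17, 3.51, 0.97, -2.16),
    "Short axis": (34.38, 40.38, 24.83, 4.2, 1.43, -2.27),
    "Red mean": (103.42, 161.97, 51.16, 27.48, 2.13, -1.90),
    "Green mean": (68.64, 113.6, 30.161, 22.40, 2.01, -1.72),
    "Blue mean": (41.91, 74.33, 19.13, 15.37, 2.11, -1.48),
    "Greyscale mean": (70.99, 114.18, 33.15, 21.52, 2.01, -1.76),
}

#: Published Pearson correlations between each trait and cap weight, ranked
#: highest to lowest.  Two traits (Roundness, Short axis) fell below the
#: |r| < 0.01 exclusion cut and carry no published value.
CORRELATION_RANKING: dict[str, float] = {
    "Perimeter": 0.91,
    "Area": 0.90,
    "Greyscale mean": 0.74,
    "External rectangular width": 0.63,
    "Long axis": 0.56,
    "External rectangular length": 0.51,
    "Red mean": 0.30,
    "Blue mean": 0.26,
    "Green mean": 0.04,
}

#: Correlation magnitude below which a trait is excluded from model inputs.
CORRELATION_EXCLUSION_CUT = 0.01

#: Fixed nested input groups for the weight model (largest to smallest).
INPUT_GROUPS: dict[str, tuple[str, ...]] = {
    "M1": ("Area", "Perimeter", "External rectangular width", "Long axis"),
    "M2": ("Area", "Perimeter", "External rectangular width"),
    "M3": ("Area", "Perimeter"),
    "M4": ("Perimeter",),
}

#: Millimetres represented by one pixel at the rig's fixed working distance.
DEFAULT_MM_PER_PX = 0.043
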