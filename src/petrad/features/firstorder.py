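"""The 18 first-order intensity features.

All features except Entropy and Uniformity are computed from the raw
in-mask SUV values; Entropy and Uniformity come from the discretized gray
levels and therefore depend on the binning scheme.  Moments are population
moments; Kurtosis is the non-excess (Pearson) form.  A constant ROI takes
the limiting values Skewness = Kurtosis = 0, Entropy = 0, Uniformity = 1.
"""

from __future__ import annotations

import numpy as np

from ..images import ROIMask, SUVImage
from ..segmentation import DiscretizedROI

__all__ = ["first_order_features", "FIRST_ORDER_NAMES", "BINNING_DEPENDENT_FIRST_ORDER"]

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

#: the two first-order features that depend on the discretization scheme
BINNING_DEPENDENT_FIRST_ORDER: tuple[str, ...] = ("Entropy", "Uniformity")


def first_order_features(
    image: SUVImage, mask: ROIMask, disc: DiscretizedROI
) -> dict[str, float]:
    mask.check_aligned(image)
    x = image.values[mask.values]
    if x.size == 0:
        raise ValueError("mask is empty")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    if var > 0:
        m2 = var
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        skew = kurt = 0.0  # degenerate single-value distribution

    levels = disc.levels
    p = np.bincount(levels)[1:] / levels.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) + 0.0  # normalize -0.0
    uniformity = float((p ** 2).sum())

    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": image.voxel_volume_mm3 * float((x ** 2).sum()),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": var,
        "Uniformity": uniformity,
    }
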