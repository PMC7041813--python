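"""Metabolic tumour volume segmentation and SUV discretization.

Two auto-segmentation rules are applied inside a manually drawn VOI:

* absolute: keep voxels strictly **above** an SUV threshold (default 2.5),
  yielding MTV2.5;
* relative: keep voxels **at least** a fraction (default 40%) of the VOI
  SUVmax, yielding MTV40.

Both rules are pure thresholding; no connected-component filtering is
applied (the VOI is assumed to isolate the primary tumour).

Before texture matrices are built, in-mask SUVs are discretized to integer
gray levels 1..Ng either with a fixed bin width in SUV units (bins anchored
at SUV 0, bin k covering [(k-1)w, k*w)) or with a fixed bin count spanning
the in-mask [min, max] range.  Fixed-bin-count levels are invariant under
positive affine maps of the intensities; fixed-bin-width levels are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import ROIMask, SUVImage

__all__ = [
    "SegmentationError",
    "DiscretizedROI",
    "segment_absolute",
    "segment_relative",
    "mask_volume_cc",
    "discretize_fixed_bin_width",
    "discretize_fixed_bin_count",
]


class SegmentationError(ValueError):
    pass


def segment_absolute(image: SUVImage, voi: ROIMask, threshold: float = 2.5) -> ROIMask:
    """Voxels inside the VOI with SUV strictly above ``threshold`` (MTV2.5)."""
    voi.check_aligned(image)
    if voi.n_voxels == 0:
        raise SegmentationError("VOI is empty")
    sel = voi.values & (image.values > threshold)
    if not sel.any():
        raise SegmentationError(f"no voxel above threshold SUV={threshold}")
    return ROIMask(sel, spacing=image.spacing, role="MTV25", origin=image.origin)


def segment_relative(image: SUVImage, voi: ROIMask, fraction: float = 0.40) -> ROIMask:
    """Voxels inside the VOI at least ``fraction`` of the VOI SUVmax (MTV40).

    Always contains the maximum voxel ("at least" => inclusive >=).
    """
    voi.check_aligned(image)
    if voi.n_voxels == 0:
        raise SegmentationError("VOI is empty")
    suv_max = float(image.values[voi.values].max())
    sel = voi.values & (image.values >= fraction * suv_max)
    return ROIMask(sel, spacing=image.spacing, role="MTV40", origin=image.origin)


def mask_volume_cc(mask: ROIMask) -> float:
    """Voxel-count volume in cc (empty mask -> 0)."""
    return mask.n_voxels * mask.voxel_volume_cc


@dataclass
class DiscretizedROI:
    """Integer gray levels over the voxels of a mask.

    ``level_grid`` holds levels 1..Ng at in-mask voxels and 0 elsewhere.
    For the fixed-bin-width scheme the occupied raw bins (anchored at SUV 0)
    are compacted to consecutive levels; ``raw_bins[k-1]`` recovers the raw
    bin index of level k.  For fixed-bin-count, ``raw_bins`` is 1..Ng.
    """

    level_grid: np.ndarray
    mask: ROIMask
    ng: int
    method: str  # "fixed_bin_width" | "fixed_bin_count"
    bin_width: float | None = None
    n_bins: int | None = None
    raw_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def levels(self) -> np.ndarray:
        """1D array of levels over in-mask voxels."""
        return self.level_grid[self.mask.values]

    @property
    def tag(self) -> str:
        if self.method == "fixed_bin_width":
            return f"binwidth{self.bin_width:g}"
        return f"bincount{self.n_bins}"


def discretize_fixed_bin_width(
    image: SUVImage, mask: ROIMask, width: float = 0.25
) -> DiscretizedROI:
    """Discretize in-mask SUVs with bins of fixed ``width`` anchored at SUV 0.

    Raw bin of value s is floor(s/width)+1; occupied raw bins are compacted
    to consecutive levels 1..Ng (raw ids retained), so Ng grows with the
    in-mask SUV range and the scheme is *not* scale-invariant.
    """
    mask.check_aligned(image)
    if mask.n_voxels == 0:
        raise SegmentationError("mask is empty")
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    suv = image.values[mask.values]
    raw = np.floor(suv / width).astype(np.int64) + 1
    occupied, compact = np.unique(raw, return_inverse=True)
    grid = np.zeros(image.shape, dtype=np.int32)
    grid[mask.values] = compact + 1
    return DiscretizedROI(
        level_grid=grid,
        mask=mask,
        ng=len(occupied),
        method="fixed_bin_width",
        bin_width=float(width),
        raw_bins=occupied,
    )


def discretize_fixed_bin_count(
    image: SUVImage, mask: ROIMask, n_bins: int = 64
) -> DiscretizedROI:
    """Discretize in-mask SUVs into ``n_bins`` equal-width bins over [min, max].

    The minimum maps to level 1 and the maximum to level ``n_bins``; values
    on an internal edge go to the higher bin.  Invariant under positive
    affine intensity maps.  A constant ROI degenerates to Ng = 1 (warning).
    """
    mask.check_aligned(image)
    if mask.n_voxels == 0:
        raise SegmentationError("mask is empty")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    suv = image.values[mask.values]
    lo, hi = float(suv.min()), float(suv.max())
    grid = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: fixed-bin-count discretization degenerates to Ng=1")
        grid[mask.values] = 1
        return DiscretizedROI(
            level_grid=grid, mask=mask, ng=1, method="fixed_bin_count",
            n_bins=int(n_bins), raw_bins=np.array([1]),
        )
    lev = np.floor(n_bins * (suv - lo) / (hi - lo)).astype(np.int64) + 1
    lev = np.minimum(lev, n_bins)  # clamp the maximum into bin n_bins
    grid[mask.values] = lev
    return DiscretizedROI(
        level_grid=grid, mask=mask, ng=int(n_bins), method="fixed_bin_count",
        n_bins=int(n_bins), raw_bins=np.arange(1, n_bins + 1),
    )
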