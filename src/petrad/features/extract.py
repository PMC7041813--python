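"""Feature extraction over segmentation x binning configurations.

``extract_config`` computes the 105 per-configuration features for one
(mask rule, binning scheme) pair; ``extract_all`` runs the full workflow
(both segmentations x both binnings) and assembles the expanded registry
row, propagating per-configuration failures as NaN without aborting the
other configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..images import ROIMask, SUVImage
from ..segmentation import (
    DiscretizedROI,
    SegmentationError,
    discretize_fixed_bin_count,
    discretize_fixed_bin_width,
    segment_absolute,
    segment_relative,
)
from .firstorder import BINNING_DEPENDENT_FIRST_ORDER, first_order_features
from .matrices import texture_matrices
from .registry import ExtractionConfig, enumerate_feature_space
from .shape import shape_features
from .texture import texture_features

__all__ = ["extract_config", "extract_all", "ExtractionResult"]


def _segment(image: SUVImage, voi: ROIMask, mask_role: str, config: ExtractionConfig) -> ROIMask:
    if mask_role == "MTV25":
        return segment_absolute(image, voi, threshold=config.abs_threshold)
    if mask_role == "MTV40":
        return segment_relative(image, voi, fraction=config.rel_fraction)
    raise ValueError(f"unknown mask role {mask_role!r}")


def _discretize(image: SUVImage, mask: ROIMask, scheme: str, config: ExtractionConfig) -> DiscretizedROI:
    if scheme == "width":
        return discretize_fixed_bin_width(image, mask, width=config.bin_width)
    if scheme == "count":
        return discretize_fixed_bin_count(image, mask, n_bins=config.bin_count)
    raise ValueError(f"unknown binning scheme {scheme!r}")


def extract_config(
    image: SUVImage,
    voi: ROIMask,
    mask_role: str = "MTV25",
    binning: str = "count",
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """The 105 features of one configuration, keyed ``family_Name``."""
    config = config or ExtractionConfig()
    mask = _segment(image, voi, mask_role, config)
    disc = _discretize(image, mask, binning, config)
    out: dict[str, float] = {}
    for name, value in first_order_features(image, mask, disc).items():
        out[f"firstorder_{name}"] = value
    for name, value in shape_features(mask).items():
        out[f"shape_{name}"] = value
    out.update(texture_features(texture_matrices(disc)))
    return out


@dataclass
class ExtractionResult:
    """Registry-indexed feature values plus per-configuration errors."""

    features: pd.Series
    errors: dict[str, str] = field(default_factory=dict)


def extract_all(
    image: SUVImage, voi: ROIMask, config: ExtractionConfig | None = None
) -> ExtractionResult:
    """All registry features of one image.

    Segmentation and shape results are computed once per mask, texture and
    Entropy/Uniformity once per (mask, binning).  A failing configuration
    (e.g. no voxel above the absolute threshold) contributes NaN for its
    features and a recorded error message.
    """
    config = config or ExtractionConfig()
    keys = enumerate_feature_space(config)
    errors: dict[str, str] = {}

    masks: dict[str, ROIMask | None] = {}
    for role in config.masks:
        try:
            masks[role] = _segment(image, voi, role, config)
        except SegmentationError as exc:
            masks[role] = None
            errors[role] = str(exc)

    first_raw: dict[str, dict[str, float]] = {}
    shapes: dict[str, dict[str, float]] = {}
    per_bin: dict[tuple[str, str], dict[str, float]] = {}
    for role, mask in masks.items():
        if mask is None:
            continue
        shapes[role] = shape_features(mask)
        for scheme in config.binnings:
            disc = _discretize(image, mask, scheme, config)
            tag = config.binning_tag(scheme)
            fo = first_order_features(image, mask, disc)
            first_raw[role] = fo  # binning-independent entries identical across discs
            per_bin[(role, tag)] = {
                **{n: fo[n] for n in BINNING_DEPENDENT_FIRST_ORDER},
                **texture_features(texture_matrices(disc)),
            }

    values: dict[str, float] = {}
    for key in keys:
        role = key.mask if key.mask is not None else config.masks[0]
        if masks.get(role) is None:
            values[key.qualified] = np.nan
            continue
        if key.family == "shape":
            values[key.qualified] = shapes[role][key.name]
        elif key.family == "firstorder":
            if key.binning is not None:
                values[key.qualified] = per_bin[(role, key.binning)][key.name]
            else:
                values[key.qualified] = first_raw[role][key.name]
        else:
            values[key.qualified] = per_bin[(role, key.binning)][f"{key.family}_{key.name}"]
    return ExtractionResult(
        features=pd.Series(values, index=[k.qualified for k in keys], dtype=float),
        errors=errors,
    )
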