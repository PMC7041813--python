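"""The canonical feature registry and its expansion over configurations.

A single (mask, binning) configuration yields 105 named features:
18 first-order + 13 shape + 74 texture.  Expanding over the default
2 masks x 2 binnings:

* 74 texture features vary with both mask and binning            -> 296
* first-order Entropy and Uniformity vary with both              ->   8
* the other 16 first-order features vary with the mask only      ->  32
* 13 shape features vary with the mask only                      ->  26

which sums to 362.  Two first-order features are emitted once across the
two masks: Maximum (SUVmax — both masks contain the maximum voxel, so the
value is identical by construction) and Minimum (pinned by the
segmentation rule itself: ~2.5 SUV under the absolute rule, ~0.4*SUVmax
under the relative one, hence not an independent measurement per mask).
This compaction gives the canonical expanded total of 360, with SUVmax,
MTV2.5 and MTV40 present as distinct entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .firstorder import BINNING_DEPENDENT_FIRST_ORDER, FIRST_ORDER_NAMES
from .shape import SHAPE_NAMES
from .texture import TEXTURE_FEATURE_NAMES

__all__ = [
    "FeatureKey",
    "ExtractionConfig",
    "enumerate_feature_space",
    "registry_counts",
    "ALIASES",
    "DEDUP_ACROSS_MASKS",
]

#: first-order features whose value is tied to the segmentation rule and is
#: therefore emitted once across the two masks (see module docstring)
DEDUP_ACROSS_MASKS: tuple[str, ...] = ("Maximum", "Minimum")


@dataclass(frozen=True)
class FeatureKey:
    """Qualified identity of one feature-configuration combination."""

    family: str  # firstorder | shape | glcm | glrlm | glszm | gldm | ngtdm
    name: str
    mask: str | None = None     # MTV25 | MTV40 | None (shared across masks)
    binning: str | None = None  # e.g. binwidth0.25 | bincount64 | None

    @property
    def qualified(self) -> str:
        parts = [f"{self.family}_{self.name}"]
        if self.mask is not None:
            parts.append(self.mask)
        if self.binning is not None:
            parts.append(self.binning)
        return "__".join(parts)

    def __str__(self) -> str:  # pragma: no cover
        return self.qualified


@dataclass
class ExtractionConfig:
    """Segmentation, binning and registry configuration."""

    abs_threshold: float = 2.5     # SUV, strict >
    rel_fraction: float = 0.40     # of SUVmax, inclusive >=
    bin_width: float = 0.25        # SUV
    bin_count: int = 64
    masks: tuple[str, ...] = ("MTV25", "MTV40")
    binnings: tuple[str, ...] = ("width", "count")  # fixed bin width / count

    def binning_tag(self, scheme: str) -> str:
        if scheme == "width":
            return f"binwidth{self.bin_width:g}"
        if scheme == "count":
            return f"bincount{self.bin_count}"
        raise ValueError(f"unknown binning scheme {scheme!r}")

    @property
    def binning_tags(self) -> tuple[str, ...]:
        return tuple(self.binning_tag(b) for b in self.binnings)


def enumerate_feature_space(config: ExtractionConfig | None = None) -> list[FeatureKey]:
    """Ordered registry of qualified feature names for a configuration.

    With the default configuration (2 masks x 2 binnings) the registry has
    exactly 360 entries; a single mask + single binning yields the 105
    per-configuration features.
    """
    config = config or ExtractionConfig()
    masks = config.masks
    tags = config.binning_tags
    keys: list[FeatureKey] = []

    for name in FIRST_ORDER_NAMES:
        if name in BINNING_DEPENDENT_FIRST_ORDER:
            keys.extend(
                FeatureKey("firstorder", name, m, t) for m in masks for t in tags
            )
        elif name in DEDUP_ACROSS_MASKS and len(masks) > 1:
            keys.append(FeatureKey("firstorder", name, None, None))
        else:
            keys.extend(FeatureKey("firstorder", name, m, None) for m in masks)
    for name in SHAPE_NAMES:
        keys.extend(FeatureKey("shape", name, m, None) for m in masks)
    for qual in TEXTURE_FEATURE_NAMES:
        family, name = qual.split("_", 1)
        keys.extend(FeatureKey(family, name, m, t) for m in masks for t in tags)
    return keys


def registry_counts(config: ExtractionConfig | None = None) -> dict[str, int]:
    """Per-family entry counts of the expanded registry."""
    counts: dict[str, int] = {}
    for key in enumerate_feature_space(config):
        counts[key.family] = counts.get(key.family, 0) + 1
    counts["total"] = sum(counts.values())
    return counts


#: friendly aliases for the features the study treats as reference metrics
ALIASES: dict[str, str] = {
    "SUVmax": "firstorder_Maximum",
    "SUVmean_MTV25": "firstorder_Mean__MTV25",
    "SUVmean_MTV40": "firstorder_Mean__MTV40",
    "MTV2.5": "shape_MetabolicTumourVolume__MTV25",
    "MTV40": "shape_MetabolicTumourVolume__MTV40",
}
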