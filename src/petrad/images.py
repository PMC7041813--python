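"""In-memory containers for PET volumes and region masks.

A :class:`SUVImage` is a 3D grid of standardized-uptake values (SUV,
unitless) with isotropic-or-not voxel spacing in millimetres.  A
:class:`ROIMask` is a binary grid aligned to an image; its ``role`` records
whether it is a manually drawn volume-of-interest (``VOI``) or one of the
two auto-segmented metabolic tumour volumes (``MTV25`` from the absolute
SUV > 2.5 rule, ``MTV40`` from the relative >= 40% SUVmax rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SUVImage", "ROIMask", "AlignmentError"]

MASK_ROLES = ("VOI", "MTV25", "MTV40")


class AlignmentError(ValueError):
    """Image and mask grids do not share shape/spacing."""


@dataclass
class SUVImage:
    """3D PET volume in SUV units.

    Parameters
    ----------
    values
        3D array of finite, non-negative SUV values.
    spacing
        Voxel spacing per axis in mm, strictly positive.
    origin
        Physical coordinate of voxel (0, 0, 0), mm.  Metadata only.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0


@dataclass
class ROIMask:
    """Binary region mask aligned with a :class:`SUVImage`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    role: str = "VOI"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be binary, found {uniq[:10]}")
            arr = arr.astype(bool)
        self.values = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}, got {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def check_aligned(self, other: "SUVImage | ROIMask") -> None:
        if self.shape != other.shape:
            raise AlignmentError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise AlignmentError(f"spacing mismatch: {self.spacing} vs {other.spacing}")
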