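"""NIfTI and tabular I/O.

Images and masks travel as NIfTI (.nii / .nii.gz) with the voxel spacing
carried in the affine; the SUV values are passed through unchanged.
Masks tolerate the common {0, 255} dialect (normalized with a warning)
but reject anything genuinely non-binary.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .images import AlignmentError, ROIMask, SUVImage

__all__ = ["read_image", "read_mask", "read_image_and_mask", "write_image", "write_mask"]


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_image(path: str | Path) -> SUVImage:
    img = nib.load(str(path))
    return SUVImage(np.asarray(img.dataobj, dtype=float), spacing=_spacing_from(img))


def read_mask(path: str | Path, role: str = "VOI") -> ROIMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    uniq = np.unique(data)
    if np.array_equal(uniq, [0.0, 255.0]) or np.array_equal(uniq, [255.0]):
        warnings.warn(f"mask {path} uses {{0, 255}}; normalizing to {{0, 1}}")
        data = data / 255.0
    elif not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"mask {path} is not binary; values include {uniq[:10]}")
    return ROIMask(data.astype(bool), spacing=_spacing_from(img), role=role)


def read_image_and_mask(
    image_path: str | Path, mask_path: str | Path, role: str = "VOI"
) -> tuple[SUVImage, ROIMask]:
    image = read_image(image_path)
    mask = read_mask(mask_path, role=role)
    if image.shape != mask.shape:
        raise AlignmentError(
            f"shape mismatch: image {image.shape} vs mask {mask.shape}"
        )
    if not np.allclose(image.spacing, mask.spacing):
        raise AlignmentError(
            f"spacing mismatch: image {image.spacing} mm vs mask {mask.spacing} mm"
        )
    return image, mask


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_image(image: SUVImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), _affine(image.spacing)), str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing)), str(path)
    )
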