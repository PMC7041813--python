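"""Synthetic FDG-PET lesion phantoms and paired "repeat" scans.

The generator emulates the inputs of a 4D-PET repeatability study without
any patient data: a textured lesion (>= 10 cc) of elevated uptake embedded
in a low-uptake soft-tissue background, a dilated VOI envelope around it,
and pairs of scans that differ only by independent voxel noise and a small
sub-voxel rigid shift — the two motion-balanced mid-position
reconstructions of a respiratory-gated acquisition differ in exactly this
way (minor noise and residual tumour motion, no biological change).

Lesion geometry is a random ellipsoid with a smooth low-order angular
perturbation; intra-lesion heterogeneity is a Gaussian random field
(white noise convolved with a Gaussian kernel whose sigma is the requested
correlation length).  The lesion iso-level is calibrated so the realized
voxel volume matches the requested volume to within one voxel layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ROIMask, SUVImage

__all__ = [
    "PhantomSpec",
    "RepeatPairSpec",
    "generate_lesion_image",
    "generate_repeat_pair",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lesion phantom.

    Defaults reflect a typical locally advanced NSCLC primary on a 4 mm
    isotropic PET reconstruction: a 62 cc lesion (cohort-median metabolic
    volume) with mean uptake SUV ~ 9 against ~1 SUV background.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesion_volume_cc: float = 62.0
    base_uptake: float = 9.0
    background_uptake: float = 1.0
    texture_correlation_length: float = 8.0  # mm
    texture_amplitude: float = 1.5  # SUV s.d. of the heterogeneity field
    anisotropy: float = 0.4  # max log-range of ellipsoid semi-axis ratios
    perturbation: float = 0.12  # relative amplitude of the angular perturbation
    voi_dilation_voxels: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.lesion_volume_cc < 10:
            raise ValueError(
                f"lesion_volume_cc must be >= 10 cc (study exclusion), got {self.lesion_volume_cc}"
            )
        if self.base_uptake <= 2.5 + 3 * self.texture_amplitude * 0.25:
            # safety margin: the SUV>2.5 segmentation must be non-empty
            raise ValueError(
                "base_uptake too close to the 2.5 SUV threshold for the given texture_amplitude"
            )
        if self.background_uptake < 0:
            raise ValueError("background_uptake must be >= 0")
        vox_cc = float(np.prod(self.spacing)) / 1000.0
        grid_cc = vox_cc * float(np.prod(self.grid_shape))
        if self.lesion_volume_cc > 0.5 * grid_cc:
            raise ValueError(
                f"lesion of {self.lesion_volume_cc} cc does not fit a "
                f"{self.grid_shape} grid ({grid_cc:.0f} cc)"
            )


@dataclass
class RepeatPairSpec:
    """Noise and residual-motion parameters of a paired repeat scan."""

    noise_sigma: float = 0.4  # SUV s.d. of additive voxel noise per scan
    shift_mm: tuple[float, float, float] = (1.0, -0.8, 0.6)
    seed: int = 0

    def validate(self, spacing: tuple[float, float, float]) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for d, s in zip(self.shift_mm, spacing):
            if abs(d) >= s:
                raise ValueError(
                    f"shift {self.shift_mm} mm must stay below one voxel {spacing} mm"
                )


def _correlated_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field, Gaussian correlation."""
    white = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def generate_lesion_image(
    spec: PhantomSpec, return_support: bool = False
) -> tuple[SUVImage, ROIMask] | tuple[SUVImage, ROIMask, np.ndarray]:
    """Generate one phantom and its VOI envelope.

    Returns the SUV image and a VOI mask (dilated lesion support); with
    ``return_support`` also the boolean lesion support grid (the
    volume-calibrated region that carries full lesion uptake).
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    vox_cc = float(np.prod(spacing)) / 1000.0
    target_vox = spec.lesion_volume_cc / vox_cc

    # physical coordinates centred on the grid midpoint
    axes = [(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*axes, indexing="ij")

    # random ellipsoid orientation + semi-axis ratios
    log_ratios = rng.uniform(-spec.anisotropy, spec.anisotropy, size=3)
    ratios = np.exp(log_ratios - log_ratios.mean())
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    pts = np.stack([x, y, z], axis=-1) @ q  # rotated coordinates
    r_ell = np.sqrt(((pts / ratios) ** 2).sum(axis=-1))  # ellipsoidal radius, mm

    # smooth low-order angular perturbation: quadratic form of the unit vector
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(r_ell[..., None] > 0, pts / np.maximum(r_ell[..., None], 1e-9), 0.0)
    a = rng.standard_normal((3, 3))
    a = (a + a.T) / 2
    pert = np.einsum("...i,ij,...j->...", u, a, u)
    pert /= max(np.abs(pert).max(), 1e-9)
    radius_field = r_ell * (1.0 + spec.perturbation * pert)

    # iso-level calibrated so the voxel count matches the requested volume
    flat = np.sort(radius_field.ravel())
    k = int(round(target_vox))
    if k < 1 or k > flat.size:
        raise ValueError("lesion volume not representable on this grid")
    iso = flat[k - 1]
    lesion = radius_field <= iso

    # intra-lesion heterogeneity: Gaussian random field at the stated
    # correlation length, plus mild background noise
    sigma_vox = spec.texture_correlation_length / spacing
    texture = _correlated_field(rng, shape, sigma_vox) * spec.texture_amplitude
    background = spec.background_uptake * np.ones(shape)
    background += 0.05 * spec.background_uptake * rng.standard_normal(shape)

    # blend lesion into background with a smoothed support (partial-volume-like edge)
    w = ndimage.gaussian_filter(lesion.astype(float), sigma=0.7)
    w[lesion] = 1.0  # interior keeps full lesion contrast
    lesion_uptake = spec.base_uptake + texture
    values = np.clip(background + w * (lesion_uptake - background), 0.0, None)

    image = SUVImage(values, spacing=tuple(spacing), origin=(0.0, 0.0, 0.0))
    voi = ndimage.binary_dilation(lesion, iterations=spec.voi_dilation_voxels)
    voi_mask = ROIMask(voi, spacing=tuple(spacing), role="VOI")
    if return_support:
        return image, voi_mask, lesion
    return image, voi_mask


def generate_repeat_pair(
    image: SUVImage, voi: ROIMask, spec: RepeatPairSpec
) -> tuple[SUVImage, SUVImage]:
    """Two repeat scans of one phantom.

    Scan A = image + noise; scan B = image resampled under a sub-voxel
    rigid shift (trilinear) + independent noise.  SUV clipped at 0.
    """
    voi.check_aligned(image)
    spec.validate(image.spacing)
    rng = np.random.default_rng(spec.seed)
    noise_a = rng.standard_normal(image.shape) * spec.noise_sigma
    noise_b = rng.standard_normal(image.shape) * spec.noise_sigma
    shift_vox = [d / s for d, s in zip(spec.shift_mm, image.spacing)]
    if any(shift_vox):
        shifted = ndimage.shift(image.values, shift=shift_vox, order=1, mode="nearest")
    else:
        shifted = image.values
    scan_a = np.clip(image.values + noise_a, 0.0, None)
    scan_b = np.clip(shifted + noise_b, 0.0, None)
    return (
        SUVImage(scan_a, spacing=image.spacing, origin=image.origin),
        SUVImage(scan_b, spacing=image.spacing, origin=image.origin),
    )
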