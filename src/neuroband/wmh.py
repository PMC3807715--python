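"""White-matter-hyperintensity segmentation by Gaussian intensity modelling.

The in-brain intensity histogram of a FLAIR-like volume is modelled as a
single Gaussian; voxels brighter than ``mu + k * sigma`` (k = 3.5 by default)
are classified as hyperintense.  Lesion load is the voxel count times the
voxel volume.  A companion step replaces lesion voxels in the T1 volume by
the mean intensity of the normal tissue shell surrounding each lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_K = 3.5
DEFAULT_VOXEL_VOLUME = 1.44  # mm^3
_MAD_TO_SIGMA = 1.4826


@dataclass
class VolumeImage:
    """A 3-D intensity volume with its brain mask and voxel volume (mm^3)."""

    voxels: np.ndarray
    voxel_volume: float = DEFAULT_VOXEL_VOLUME
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.voxels.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.voxels.shape:
                raise ValueError("brain_mask shape must match voxels")


@dataclass
class GaussianModel:
    """Gaussian background-intensity model with threshold multiplier ``k``."""

    mu: float
    sigma: float
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def threshold(self) -> float:
        return self.mu + self.k * self.sigma


def fit_background(
    volume: VolumeImage, k: float = DEFAULT_K, robust: bool = False
) -> GaussianModel:
    """Fit the in-brain intensity Gaussian.

    The plain fit is the sample mean and SD of the in-mask intensities.  The
    robust variant initializes from the median and scaled MAD, trims voxels
    brighter than ``median + k * sigma_mad`` once, and refits mean/SD on the
    retained voxels — this keeps bright lesions from inflating the model.
    """
    data = volume.voxels[volume.brain_mask]
    if data.size < 100:
        raise ValueError(f"brain mask holds only {data.size} voxels; need >= 100")
    if robust:
        med = float(np.median(data))
        sigma_mad = _MAD_TO_SIGMA * float(np.median(np.abs(data - med)))
        if sigma_mad == 0:
            raise ValueError("degenerate intensity distribution (MAD = 0)")
        data = data[data <= med + k * sigma_mad]
    mu = float(data.mean())
    sigma = float(data.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate intensity distribution (sigma = 0)")
    return GaussianModel(mu=mu, sigma=sigma, k=k)


def segment_wmh(
    volume: VolumeImage, model: GaussianModel, k: float | None = None
) -> np.ndarray:
    """Boolean mask of in-brain voxels brighter than ``mu + k * sigma``."""
    thr = model.mu + (model.k if k is None else k) * model.sigma
    return volume.brain_mask & (volume.voxels > thr)


def lesion_volume(mask: np.ndarray, voxel_volume: float = DEFAULT_VOXEL_VOLUME) -> float:
    """Lesion load in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    return float(mask.sum()) * voxel_volume


def _ball(radius: int) -> np.ndarray:
    """Euclidean ball structuring element of integer ``radius`` voxels."""
    r = int(radius)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (grid**2).sum(axis=0) <= r**2


#: 26-connectivity for lesion components.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def correct_t1_intensity(
    t1: VolumeImage,
    wmh_mask: np.ndarray,
    shell_radius: int = 2,
) -> tuple[VolumeImage, list[int]]:
    """Replace lesion voxels in the T1 by the mean of their normal-tissue shell.

    For each 26-connected lesion component, the shell is the set of in-brain,
    non-lesion voxels within ``shell_radius`` voxels of the component.  A
    component with an empty shell is left unchanged and its label is returned
    in the flagged list.  Voxels outside the mask are never modified.
    """
    wmh_mask = np.asarray(wmh_mask, dtype=bool)
    if wmh_mask.shape != t1.voxels.shape:
        raise ValueError("wmh_mask shape must match the T1 volume")
    corrected = t1.voxels.copy()
    labels, n_comp = ndimage.label(wmh_mask, structure=_CONN26)
    ball = _ball(shell_radius)
    flagged: list[int] = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        shell = ndimage.binary_dilation(comp_mask, structure=ball)
        shell &= t1.brain_mask & ~wmh_mask
        if not shell.any():
            flagged.append(comp)
            continue
        corrected[comp_mask] = t1.voxels[shell].mean()
    return (
        VolumeImage(corrected, t1.voxel_volume, t1.brain_mask.copy()),
        flagged,
    )


def remove_bias_field(
    volume: VolumeImage, sigma_mm: float = 25.0, voxel_size_mm: float = 1.0
) -> VolumeImage:
    """Optional large-kernel low-pass bias division (off by default upstream).

    The in-mask volume is smoothed with a Gaussian of ``sigma_mm`` and the
    image is divided by the smooth field normalized to unit in-mask mean.
    """
    mask = volume.brain_mask.astype(float)
    sigma_vox = sigma_mm / voxel_size_mm
    smooth = ndimage.gaussian_filter(volume.voxels * mask, sigma_vox)
    weight = ndimage.gaussian_filter(mask, sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        field = np.where(weight > 1e-12, smooth / weight, np.nan)
    field = field / np.nanmean(field[volume.brain_mask])
    out = np.where(volume.brain_mask, volume.voxels / field, volume.voxels)
    return VolumeImage(out, volume.voxel_volume, volume.brain_mask.copy())
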