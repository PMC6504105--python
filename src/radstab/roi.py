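"""ROI preparation: resampling and fixed-bin-width gray-level discretization.

Preprocessing convention: intensities are resampled to 3x3x3 mm voxels
(linear interpolation; nearest-neighbor for the mask) and discretized
with a fixed bin width of 25 anchored at the ROI minimum,

    level(v) = floor((v - min_ROI) / 25) + 1,

so a constant ROI has exactly one gray level.  Arrays are indexed
(i, j, k) with ``spacing`` giving the physical size of a step along each
axis, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

DEFAULT_SPACING = (3.0, 3.0, 3.0)
DEFAULT_BIN_WIDTH = 25.0


def _to_sitk(array: np.ndarray, spacing) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); our convention is axis 0 slowest,
    # so the spacing tuple is reversed on the way in and out.
    img = sitk.GetImageFromArray(np.asarray(array))
    img.SetSpacing(tuple(float(s) for s in reversed(spacing)))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple[float, ...]]:
    return sitk.GetArrayFromImage(img), tuple(reversed(img.GetSpacing()))


def read_image(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read an NRRD or NIfTI volume; returns (array, spacing)."""
    return _from_sitk(sitk.ReadImage(str(path)))


def write_image(path, array: np.ndarray, spacing) -> None:
    """Write an NRRD (.nrrd) or NIfTI (.nii/.nii.gz) volume."""
    sitk.WriteImage(_to_sitk(array, spacing), str(path))


def resample_to_spacing(array: np.ndarray, spacing, new_spacing, is_mask: bool = False) -> np.ndarray:
    """Resample a volume to a new voxel spacing (identity transform)."""
    img = _to_sitk(array.astype(np.float64) if not is_mask else array.astype(np.uint8), spacing)
    in_size = np.array(img.GetSize(), dtype=float)
    in_sp = np.array(img.GetSpacing())
    out_sp = np.array([float(s) for s in reversed(new_spacing)])
    out_size = np.maximum(np.ceil(in_size * in_sp / out_sp).astype(int), 1)
    res = sitk.Resample(
        img,
        [int(s) for s in out_size],
        sitk.Transform(),
        sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear,
        img.GetOrigin(),
        tuple(out_sp),
        img.GetDirection(),
        0,
        img.GetPixelID(),
    )
    out, _ = _from_sitk(res)
    return out.astype(bool) if is_mask else out


@dataclass
class PreparedROI:
    """Resampled intensity grid, mask, and discretized gray levels."""

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    bin_width: float
    levels: np.ndarray  # int levels >= 1 inside the mask, 0 outside

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def intensities(self) -> np.ndarray:
        return self.image[self.mask]

    @property
    def mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]

    @property
    def n_levels(self) -> int:
        return int(self.mask_levels.max())


def discretize(image: np.ndarray, mask: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels anchored at the in-mask minimum."""
    levels = np.zeros(image.shape, dtype=np.int64)
    vals = image[mask]
    levels[mask] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return levels


def prepare_roi(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    new_spacing=DEFAULT_SPACING,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PreparedROI:
    """Resample image+mask to isotropic spacing and discretize the ROI.

    Resampling is skipped when the input is already on the target grid
    (keeps integer-voxel translation invariance exact).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share geometry")
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = tuple(float(s) for s in spacing)
    new_spacing = tuple(float(s) for s in new_spacing)
    if spacing != new_spacing:
        image = resample_to_spacing(image, spacing, new_spacing, is_mask=False)
        mask = resample_to_spacing(mask, spacing, new_spacing, is_mask=True)
        if not mask.any():
            raise ValueError("mask is empty after resampling")
    levels = discretize(image, mask, bin_width)
    return PreparedROI(image, mask, new_spacing, float(bin_width), levels)
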