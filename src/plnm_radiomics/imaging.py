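"""Volume containers, NIfTI I/O and the image preprocessing used before feature
extraction: ADC computation from two diffusion b-values, resampling onto a
reference grid, z-score intensity normalization and fixed-bin-width gray-level
discretization.

Conventions
-----------
Arrays are indexed ``(x, y, z)`` with ``spacing`` and ``origin`` given in mm in
the same axis order.  The package assumes axis-aligned grids (no direction
matrix); this is sufficient for phantom cohorts and for pre-aligned clinical
exports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Tuple

import nibabel as nib
import numpy as np
import SimpleITK as sitk

Modality = Literal["T2", "ADC", "DWI-b100", "DWI-b1000", "mask", "derived"]

#: floor applied to diffusion signals before taking logarithms
SIGNAL_FLOOR = 1e-8


class AlignmentError(ValueError):
    """Raised when two volumes expected on the same grid disagree."""


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable information (zero spread, empty mask)."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical grid metadata.

    Parameters
    ----------
    values : (nx, ny, nz) float array
    spacing : voxel size in mm per axis (all > 0)
    origin : physical position of voxel (0,0,0) in mm
    modality : free-form tag; ``T2``/``ADC`` are the two used for extraction
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "derived"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("ImageVolume requires a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """Same grid, new voxel data."""
        return ImageVolume(
            np.asarray(values, dtype=float),
            self.spacing,
            self.origin,
            modality if modality is not None else self.modality,
        )

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class Mask:
    """Binary region-of-interest aligned to a reference :class:`ImageVolume`."""

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("Mask requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise DegenerateInputError("mask has no foreground voxels")


@dataclass
class DiscretizedVolume:
    """Gray levels in ``1..n_levels`` defined on a mask (0 outside)."""

    levels: np.ndarray
    n_levels: int
    bin_width: float
    mask: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz); integer arrays stay integer."""
    data = volume.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_from(volume.spacing, volume.origin))
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike, modality: str = "derived") -> ImageVolume:
    """Read a NIfTI volume; spacing/origin recovered from the affine diagonal."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error classes vary
        raise ValueError(f"cannot read {path!r} as NIfTI: {exc}") from exc
    aff = img.affine
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin, modality)


def write_mask(mask: Mask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine_from(mask.spacing, mask.origin)
    )
    nib.save(img, os.fspath(path))


def read_mask(path: str | os.PathLike) -> Mask:
    vol = read_volume(path, modality="mask")
    return Mask(vol.values > 0.5, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# ADC computation
# ---------------------------------------------------------------------------

def compute_adc(
    s_low: ImageVolume,
    s_high: ImageVolume,
    b_low: float = 100.0,
    b_high: float = 1000.0,
) -> ImageVolume:
    """Mono-exponential ADC map from two diffusion-weighted acquisitions.

    ``ADC = ln(S_low / S_high) / (b_high - b_low)`` voxelwise, in mm^2/s for
    b-values in s/mm^2.  Signals are clamped to a small positive floor before
    the logarithm, so zero-signal voxels give a finite (zero) ADC.
    """
    if not s_low.same_grid(s_high):
        raise AlignmentError("b-value volumes are not on the same grid")
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    lo = np.maximum(s_low.values, SIGNAL_FLOOR)
    hi = np.maximum(s_high.values, SIGNAL_FLOOR)
    adc = np.log(lo / hi) / (b_high - b_low)
    return s_low.with_values(adc, modality="ADC")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERPOLATORS = {
    "bspline": sitk.sitkBSpline,
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def _to_sitk(volume: ImageVolume) -> sitk.Image:
    # SimpleITK expects (z, y, x) arrays
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    return img


def resample_to_reference(
    moving: ImageVolume,
    reference: ImageVolume,
    interpolator: str = "bspline",
) -> ImageVolume:
    """Resample ``moving`` onto the grid of ``reference`` (identity transform).

    The phantom cohorts (and pre-registered clinical exports) share a world
    frame, so only grid resampling is performed; estimating a registration
    transform is out of scope.  Use ``interpolator='nearest'`` for masks.
    """
    if interpolator not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolator {interpolator!r}")
    if moving.same_grid(reference):
        return reference.with_values(moving.values.copy(), modality=moving.modality)
    out = sitk.Resample(
        _to_sitk(moving),
        _to_sitk(reference),
        sitk.Transform(),
        _INTERPOLATORS[interpolator],
        0.0,
        sitk.sitkFloat64,
    )
    values = sitk.GetArrayFromImage(out).T
    return reference.with_values(values, modality=moving.modality)


def resample_mask_to_reference(mask: Mask, reference: ImageVolume) -> Mask:
    vol = ImageVolume(mask.values.astype(float), mask.spacing, mask.origin, "mask")
    res = resample_to_reference(vol, reference, interpolator="nearest")
    return Mask(res.values > 0.5, reference.spacing, reference.origin)


# ---------------------------------------------------------------------------
# Intensity normalization and discretization
# ---------------------------------------------------------------------------

def normalize_intensity(
    volume: ImageVolume,
    mask: Mask | None = None,
    scale: float = 100.0,
) -> ImageVolume:
    """Z-score the image and multiply by ``scale`` (default 100).

    Statistics come from the whole image by default; pass a mask to use
    region statistics instead.  Output has mean 0 and standard deviation
    ``scale`` over the region the statistics were computed on.
    """
    x = volume.values.astype(float)
    region = x[mask.values] if mask is not None else x
    sd = float(region.std())
    if sd == 0:
        raise DegenerateInputError("cannot normalize a constant image (sd = 0)")
    return volume.with_values(scale * (x - float(region.mean())) / sd)


def discretize(
    volume: ImageVolume,
    mask: Mask,
    bin_width: float = 25.0,
) -> DiscretizedVolume:
    """Fixed-bin-width gray-level discretization over the masked voxels.

    ``level(x) = floor((x - min) / bin_width) + 1``; levels span
    ``1..n_levels`` with ``n_levels = floor((max - min) / bin_width) + 1``
    (a masked maximum that falls exactly on a bin edge opens a new top bin,
    the usual fixed-bin-width convention).  Levels are 0 outside the mask.
    """
    mask.require_nonempty()
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = mask.values
    x = volume.values
    lo = float(x[m].min())
    hi = float(x[m].max())
    n_levels = int(np.floor((hi - lo) / bin_width)) + 1
    levels = np.zeros(x.shape, dtype=np.int32)
    lv = np.floor((x[m] - lo) / bin_width).astype(np.int32) + 1
    levels[m] = np.clip(lv, 1, n_levels)
    return DiscretizedVolume(levels=levels, n_levels=n_levels, bin_width=float(bin_width), mask=m)
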