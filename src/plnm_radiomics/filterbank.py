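"""The image filter bank: original plus 19 derived images.

Texture features are extracted not only from the original T2/ADC crop but from
a bank of filtered versions of it: three Laplacian-of-Gaussian scales, four
pointwise intensity transforms, a gradient-magnitude map, three 3D local
binary pattern maps and the eight sub-bands of a single-level stationary Haar
wavelet decomposition — 20 images in total, which fixes the feature-space
arithmetic downstream (107 + 19 x 93 = 1874 features per modality per VOI).

All convolution-type filters use mirror boundary handling and are
spacing-aware where a physical scale is involved (LoG sigma in mm, gradient
in intensity/mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pywt
from scipy import ndimage

from .imaging import ImageVolume

POINTWISE_KINDS = ("logarithm", "square", "squareroot", "exponential")
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LBP_MAPS = ("lbp_3D_m1", "lbp_3D_m2", "lbp_3D_k")


@dataclass
class BankConfig:
    """Which derived images to compute.

    The defaults reproduce the full 20-image bank.  ``log_sigmas_mm`` are the
    LoG scales in millimetres.
    """

    original: bool = True
    log_sigmas_mm: Sequence[float] = (0.5, 1.0, 1.5)
    pointwise: Sequence[str] = POINTWISE_KINDS
    gradient: bool = True
    lbp3d: bool = True
    wavelet: bool = True

    def __post_init__(self) -> None:
        bad = set(self.pointwise) - set(POINTWISE_KINDS)
        if bad:
            raise ValueError(f"unknown pointwise kinds: {sorted(bad)}")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")


def _sigma_name(sigma: float) -> str:
    # 0.5 -> "log_sigma_0_5", 1.0 -> "log_sigma_1_0"
    return "log_sigma_" + f"{sigma:g}".replace(".", "_") + ("_0" if float(sigma) == int(sigma) else "")


def enumerate_feature_images(config: BankConfig | None = None) -> List[str]:
    """Canonical ordered names of the images the bank produces."""
    config = config or BankConfig()
    names: List[str] = []
    if config.original:
        names.append("original")
    names += [_sigma_name(s) for s in config.log_sigmas_mm]
    names += list(config.pointwise)
    if config.gradient:
        names.append("gradient")
    if config.lbp3d:
        names += list(LBP_MAPS)
    if config.wavelet:
        names += [f"wavelet_{b}" for b in WAVELET_BANDS]
    return names


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def apply_log_of_gaussian(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    The sampled derivative kernel is DC-corrected (its taps do not sum
    exactly to zero) so constant images map to exactly zero, and the output
    is scale-normalized by ``sigma^2`` as usual for blob detection.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    x = volume.values.astype(float)
    raw = ndimage.gaussian_laplace(x, sigma=sigma_vox, mode="mirror")
    # kernel-tap sum == response to a constant 1 (mirror of a constant is
    # itself); subtracting ksum * x zeroes the DC response
    ksum = float(ndimage.gaussian_laplace(np.ones((3, 3, 3)), sigma=sigma_vox, mode="mirror")[1, 1, 1])
    return volume.with_values((raw - ksum * x) * sigma_mm**2)


def apply_pointwise(
    volume: ImageVolume, kind: str, stats_mask: np.ndarray | None = None
) -> ImageVolume:
    """Monotone voxelwise transforms with range handling.

    log/sqrt shift the image to non-negative first; every output is rescaled
    so its maximum magnitude equals the input's maximum magnitude (constant
    inputs map to constants untouched by the rescale).  When ``stats_mask``
    is given the shift/rescale constants come from that region only, which
    makes the transform of masked voxels independent of the crop box around
    them (values outside the region are clamped into the transform domain).
    """
    if kind not in POINTWISE_KINDS:
        raise ValueError(f"unknown pointwise kind {kind!r}")
    x = volume.values.astype(float)
    region = x[np.asarray(stats_mask, bool)] if stats_mask is not None else x
    max_mag = float(np.abs(region).max())
    lo = float(region.min())
    if kind == "logarithm":
        y = np.log1p(np.maximum(x - lo, 0.0))
        ref = np.log1p(region - lo)
    elif kind == "squareroot":
        y = np.sqrt(np.maximum(x - lo, 0.0))
        ref = np.sqrt(region - lo)
    elif kind == "square":
        y = x**2
        ref = region**2
    else:  # exponential
        y = np.exp(np.minimum(x / max_mag, 50.0)) if max_mag > 0 else np.ones_like(x)
        ref = np.exp(region / max_mag) if max_mag > 0 else np.ones_like(region)
    ymax = float(np.abs(ref).max())
    if ymax > 0 and max_mag > 0:
        y = y * (max_mag / ymax)
    return volume.with_values(y)


def apply_gradient(volume: ImageVolume) -> ImageVolume:
    """Gradient-magnitude map from spacing-aware central differences."""
    padded = np.pad(volume.values.astype(float), 1, mode="reflect")
    grads = np.gradient(padded, *volume.spacing)
    mag = np.sqrt(sum(g**2 for g in grads))[1:-1, 1:-1, 1:-1]
    return volume.with_values(mag)


def apply_wavelet_haar(volume: ImageVolume) -> Dict[str, ImageVolume]:
    """Single-level undecimated (stationary) 3D Haar transform.

    Returns the eight sub-bands ``LLL .. HHH`` on the original grid; the band
    letters follow axis order (x, y, z), L = approximation, H = detail.
    """
    x = volume.values.astype(float)
    # SWT needs even extents; mirror-pad then crop back
    pads = [(0, s % 2) for s in x.shape]
    xp = np.pad(x, pads, mode="reflect") if any(p[1] for p in pads) else x
    coeffs = pywt.swtn(xp, wavelet="haar", level=1, start_level=0, norm=False)[0]
    out: Dict[str, ImageVolume] = {}
    sl = tuple(slice(0, s) for s in x.shape)
    for key, arr in coeffs.items():
        band = "".join("L" if c == "a" else "H" for c in key)
        out[f"wavelet_{band}"] = volume.with_values(arr[sl])
    return out


# 26-neighbourhood offsets and their unit direction vectors, used as the
# spherical sampling set for the 3D local binary patterns
_NB_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
)
_NB_UNIT = _NB_OFFSETS / np.linalg.norm(_NB_OFFSETS, axis=1, keepdims=True)


def apply_lbp3d(volume: ImageVolume) -> Dict[str, ImageVolume]:
    """Spherical local-binary-pattern maps.

    Each voxel is compared with its 26 sphere-sampled neighbours
    (``b_k = 1`` if neighbour >= centre).  The binary pattern is summarised
    rotation-invariantly by the energies of its first two angular-moment
    levels — the dipole norm ``m1 = |sum b_k u_k|`` and the traceless
    quadrupole Frobenius norm ``m2`` — plus a local-kurtosis map ``k`` of the
    neighbour intensities (0 where the neighbourhood is flat).
    """
    x = np.pad(volume.values.astype(float), 1, mode="reflect")
    core = tuple(slice(1, 1 + s) for s in volume.shape)
    center = x[core]
    dip = np.zeros(volume.shape + (3,))
    quad = np.zeros(volume.shape + (3, 3))
    s1 = np.zeros(volume.shape)
    s2 = np.zeros(volume.shape)
    s3 = np.zeros(volume.shape)
    s4 = np.zeros(volume.shape)
    eye3 = np.eye(3) / 3.0
    for off, u in zip(_NB_OFFSETS, _NB_UNIT):
        nb = x[tuple(slice(1 + o, 1 + o + s) for o, s in zip(off, volume.shape))]
        b = (nb >= center).astype(float)
        dip += b[..., None] * u
        quad += b[..., None, None] * (np.outer(u, u) - eye3)
        s1 += nb
        s2 += nb**2
        s3 += nb**3
        s4 += nb**4
    n = len(_NB_OFFSETS)
    m1 = np.linalg.norm(dip, axis=-1)
    m2 = np.linalg.norm(quad.reshape(volume.shape + (9,)), axis=-1)
    mu = s1 / n
    var = np.maximum(s2 / n - mu**2, 0.0)
    m4 = s4 / n - 4 * mu * s3 / n + 6 * mu**2 * s2 / n - 3 * mu**4
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(var > 1e-12, m4 / np.maximum(var, 1e-300) ** 2, 0.0)
    return {
        "lbp_3D_m1": volume.with_values(m1),
        "lbp_3D_m2": volume.with_values(m2),
        "lbp_3D_k": volume.with_values(kurt),
    }


# ---------------------------------------------------------------------------
# The full bank
# ---------------------------------------------------------------------------

def apply_filter_bank(
    volume: ImageVolume,
    config: BankConfig | None = None,
    stats_mask: np.ndarray | None = None,
) -> Dict[str, ImageVolume]:
    """Compute every enabled derived image; keys follow
    :func:`enumerate_feature_images` order.  ``stats_mask`` (the VOI) fixes
    the pointwise-transform constants to a crop-independent region."""
    config = config or BankConfig()
    out: Dict[str, ImageVolume] = {}
    if config.original:
        out["original"] = volume
    for s in config.log_sigmas_mm:
        out[_sigma_name(s)] = apply_log_of_gaussian(volume, s)
    for kind in config.pointwise:
        out[kind] = apply_pointwise(volume, kind, stats_mask)
    if config.gradient:
        out["gradient"] = apply_gradient(volume)
    if config.lbp3d:
        out.update(apply_lbp3d(volume))
    if config.wavelet:
        out.update(apply_wavelet_haar(volume))
    order = enumerate_feature_images(config)
    return {name: out[name] for name in order}
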