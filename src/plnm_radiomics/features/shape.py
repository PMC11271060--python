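"""Morphological (shape) features of a binary VOI.

Shape is intensity-free and computed once per VOI on the original image grid.
Surface quantities come from a marching-cubes mesh of the mask (level 0.5,
physical spacing); axis lengths from the eigenvalues of the physical
voxel-coordinate covariance, with the radiological convention
``axis length = 4 * sqrt(eigenvalue)``.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes

from ..imaging import DegenerateInputError

SHAPE_FEATURES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]


def mask_mesh(mask: np.ndarray, spacing: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Marching-cubes surface of the (zero-padded) mask in physical mm."""
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    verts = verts - np.asarray(spacing, dtype=float)  # undo the pad offset
    return verts, faces


def _mesh_volume_area(verts: np.ndarray, faces: np.ndarray) -> Tuple[float, float]:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    cross = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    volume = np.abs((a * cross).sum() / 6.0)
    return float(volume), float(area)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 64 and points.shape[1] == 3:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # coplanar degenerate hulls
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: Sequence[float]) -> Dict[str, float]:
    """The 14 standard 3D shape features.

    The three Maximum2DDiameter features are the largest in-plane vertex
    distances ignoring, respectively, the slice (z), column (x) and row (y)
    axis.  Point-like masks (zero covariance) report Elongation and
    Flatness as 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    spacing = np.asarray(spacing, dtype=float)

    voxel_volume = float(mask.sum() * spacing.prod())
    verts, faces = mask_mesh(mask, spacing)
    mesh_volume, surface_area = _mesh_volume_area(verts, faces)

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    coords = np.argwhere(mask) * spacing  # physical voxel centres
    if len(coords) > 1:
        evals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        evals = np.maximum(evals, 0.0)
    else:
        evals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(evals)).tolist()
    elongation = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else 1.0
    flatness = float(np.sqrt(evals[2] / evals[0])) if evals[0] > 0 else 1.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_pairwise(verts[:, :2]),   # x-y plane
        "Maximum2DDiameterColumn": _max_pairwise(verts[:, 1:]),  # y-z plane
        "Maximum2DDiameterRow": _max_pairwise(verts[:, ::2]),    # x-z plane
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
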