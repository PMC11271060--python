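"""First-order (intensity histogram) features over a masked region."""

from __future__ import annotations

from typing import Dict

import numpy as np

from ..imaging import DegenerateInputError

FIRSTORDER_FEATURES = [
    "Mean", "Median", "Variance", "Skewness", "Kurtosis", "Energy",
    "TotalEnergy", "Entropy", "Minimum", "Maximum", "Range", "10Percentile",
    "90Percentile", "InterquartileRange", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Uniformity",
]


def first_order_features(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    voxel_shift: float = 300.0,
    voxel_volume: float = 1.0,
) -> Dict[str, float]:
    """The 18 standard first-order features.

    ``voxel_shift`` is added to the intensities only inside the Energy,
    TotalEnergy and RootMeanSquared formulas (the "voxel array shift"
    convention, which keeps these magnitude features positive for z-scored
    images).  Entropy and Uniformity use a fixed-bin-width histogram with the
    same ``bin_width`` as the texture discretization.  Degenerate regions
    (zero variance) report Skewness and Kurtosis as 0.
    """
    x = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise DegenerateInputError("empty mask")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)

    if var > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    lo, hi = float(x.min()), float(x.max())
    n_bins = int(np.floor((hi - lo) / bin_width)) + 1
    levels = np.clip(np.floor((x - lo) / bin_width).astype(int), 0, n_bins - 1)
    p = np.bincount(levels, minlength=n_bins).astype(float) / n
    nz = p[p > 0]

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0

    shifted_sq = (x + voxel_shift) ** 2
    energy = float(shifted_sq.sum())
    return {
        "Mean": mean,
        "Median": float(p50),
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Minimum": lo,
        "Maximum": hi,
        "Range": hi - lo,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(shifted_sq.mean())),
        "Uniformity": float((p**2).sum()),
    }
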