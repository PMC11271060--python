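"""Gray-level texture-matrix feature families.

Five families are computed from a fixed-bin-width discretized volume over a
mask: co-occurrence (GLCM, 24 features), run length (GLRLM, 16), size zone
(GLSZM, 16), neighbourhood gray-tone difference (NGTDM, 5) and gray-level
dependence (GLDM, 14).  Directional families (GLCM, GLRLM) use the 13 unique
3D directions at Chebyshev distance 1 and average feature values over
directions; neighbourhood families use the full 26-neighbourhood.

Degenerate conventions (single gray level, no neighbours) follow the common
extraction-software sentinels and are noted per feature.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from scipy import ndimage

from ..imaging import DegenerateInputError, DiscretizedVolume

_EPS = np.spacing(1.0)

#: the 13 unique direction offsets (first non-zero component positive)
DIRECTIONS_13 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
]

#: all 26 neighbour offsets
OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _neighbor(arr: np.ndarray, d, fill) -> np.ndarray:
    """``out[v] = arr[v + d]`` with out-of-bounds positions set to ``fill``."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src, dst = [], []
    for o, s in zip(d, arr.shape):
        if o >= 0:
            src.append(slice(o, s))
            dst.append(slice(0, s - o))
        else:
            src.append(slice(0, s + o))
            dst.append(slice(-o, s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _check(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, int]:
    mask = np.asarray(disc.mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    return np.asarray(disc.levels), mask, int(disc.n_levels)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_FEATURES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]


def glcm_matrices(disc: DiscretizedVolume) -> List[np.ndarray]:
    """Normalized symmetric co-occurrence matrix per direction (may skip
    directions with no valid voxel pair)."""
    lvl, mask, ng = _check(disc)
    mats = []
    for d in DIRECTIONS_13:
        nb_ok = _neighbor(mask, d, False)
        nb_lvl = _neighbor(lvl, d, 0)
        both = mask & nb_ok
        if not both.any():
            continue
        counts = np.zeros((ng, ng))
        np.add.at(counts, (lvl[both] - 1, nb_lvl[both] - 1), 1.0)
        counts = counts + counts.T
        mats.append(counts / counts.sum())
    return mats


def _glcm_features_one(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py (symmetric)
    mu = float((ii * p).sum())  # JointAverage; mu_x == mu_y
    sig2 = float(((ii - mu) ** 2 * p).sum())
    sig = np.sqrt(sig2)

    # difference / sum distributions
    kd = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in kd])
    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ks])

    da = float((kd * p_diff).sum())
    feats: Dict[str, float] = {}
    feats["Autocorrelation"] = float((ii * jj * p).sum())
    feats["ClusterProminence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())
    feats["ClusterShade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    feats["ClusterTendency"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    feats["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    # degenerate single-level region: correlation undefined -> 1 (perfectly
    # dependent by convention)
    feats["Correlation"] = (
        1.0 if sig2 == 0 else float(((ii - mu) * (jj - mu) * p).sum() / sig2)
    )
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + _EPS))[p_diff > 0].sum())
    feats["DifferenceVariance"] = float(((kd - da) ** 2 * p_diff).sum())
    feats["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    feats["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    feats["Idmn"] = float((p / (1.0 + ((ii - jj) ** 2) / ng**2)).sum())
    feats["Idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())

    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nzm = pxpy > 0
    hxy2 = float(-(pxpy[nzm] * np.log2(pxpy[nzm])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    feats["Imc1"] = 0.0 if hx == 0 else (hxy - hxy1) / hx
    feats["Imc2"] = 0.0 if hxy2 < hxy else float(np.sqrt(1 - np.exp(-2 * (hxy2 - hxy))))

    invvar = p / np.where((ii - jj) == 0, 1.0, (ii - jj) ** 2).astype(float)
    feats["InverseVariance"] = float(invvar[ii != jj].sum())
    feats["JointAverage"] = mu
    feats["JointEnergy"] = float((p**2).sum())
    feats["JointEntropy"] = hxy

    # MCC: sqrt of the second-largest eigenvalue of Q
    if ng == 1:
        feats["MCC"] = 1.0
    else:
        # Q[i,j] = sum_k p[i,k] p[j,k] / (px[i] py[k])
        safe_px = np.where(px == 0, 1.0, px)
        q = (p[:, None, :] * p[None, :, :] / (safe_px[:, None, None] * safe_px[None, None, :])).sum(axis=2)
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        second = ev[-2] if len(ev) > 1 else ev[-1]
        feats["MCC"] = float(np.sqrt(max(second, 0.0)))

    feats["MaximumProbability"] = float(p.max())
    feats["SumAverage"] = float((ks * p_sum).sum())
    feats["SumEntropy"] = float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum())
    feats["SumSquares"] = sig2
    return feats


def glcm_features(disc: DiscretizedVolume) -> Dict[str, float]:
    """24 co-occurrence features averaged over the 13 directions."""
    mats = glcm_matrices(disc)
    if not mats:
        # single isolated voxel: no pairs at all -> flat-texture sentinels
        mats = [np.ones((1, 1))]
    per_dir = [_glcm_features_one(p) for p in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_FEATURES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]


def glrlm_matrices(disc: DiscretizedVolume) -> List[np.ndarray]:
    """Run-length count matrix (levels x run length) per direction."""
    lvl, mask, ng = _check(disc)
    max_len = max(lvl.shape)
    mats = []
    for d in DIRECTIONS_13:
        nb_ok = _neighbor(mask, d, False)
        nb_lvl = _neighbor(lvl, d, 0)
        cont = mask & nb_ok & (lvl == nb_lvl)  # run continues from v to v+d
        # dist[v] = number of continuation steps remaining after v
        axis = next(a for a in range(3) if d[a] != 0)
        rem = tuple(o for a, o in enumerate(d) if a != axis)
        dist = np.zeros(lvl.shape, dtype=np.int32)
        idx = [slice(None)] * 3
        nxt_idx = [slice(None)] * 3
        for x in range(lvl.shape[axis] - 2, -1, -1):
            idx[axis] = x
            nxt_idx[axis] = x + 1
            nxt = _neighbor(dist[tuple(nxt_idx)], rem, 0)
            dist[tuple(idx)] = np.where(cont[tuple(idx)], nxt + 1, 0)
        starts = mask & ~_neighbor(cont, tuple(-o for o in d), False)
        r = np.zeros((ng, max_len))
        np.add.at(r, (lvl[starts] - 1, dist[starts]), 1.0)
        mats.append(r)
    return mats


def _rlm_style_features(r: np.ndarray, n_voxels: int, prefix: str) -> Dict[str, float]:
    """Shared formulas for run-length-shaped matrices (GLRLM / GLSZM / GLDM
    use the same algebra with different names)."""
    nr = r.sum()
    p = r / nr
    ng, nl = r.shape
    iv = np.arange(1, ng + 1)[:, None].astype(float)
    jv = np.arange(1, nl + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float((iv[:, 0] * pg).sum())
    mu_j = float((jv[0, :] * pl).sum())
    nzp = p[p > 0]
    return {
        f"{prefix}Short": float((p / jv**2).sum()),
        f"{prefix}Long": float((p * jv**2).sum()),
        f"{prefix}GLN": float((r.sum(axis=1) ** 2).sum() / nr),
        f"{prefix}GLNN": float((pg**2).sum()),
        f"{prefix}LN": float((r.sum(axis=0) ** 2).sum() / nr),
        f"{prefix}LNN": float((pl**2).sum()),
        f"{prefix}Pct": float(nr / n_voxels),
        f"{prefix}GLV": float((p * (iv - mu_i) ** 2).sum()),
        f"{prefix}LV": float((p * (jv - mu_j) ** 2).sum()),
        f"{prefix}Entropy": float(-(nzp * np.log2(nzp)).sum()),
        f"{prefix}LGL": float((p / iv**2).sum()),
        f"{prefix}HGL": float((p * iv**2).sum()),
        f"{prefix}ShortLGL": float((p / (iv**2 * jv**2)).sum()),
        f"{prefix}ShortHGL": float((p * iv**2 / jv**2).sum()),
        f"{prefix}LongHGL": float((p * iv**2 * jv**2).sum()),
        f"{prefix}LongLGL": float((p * jv**2 / iv**2).sum()),
    }


_GLRLM_MAP = {
    "ShortRunEmphasis": "Short", "LongRunEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN", "GrayLevelNonUniformityNormalized": "GLNN",
    "RunLengthNonUniformity": "LN", "RunLengthNonUniformityNormalized": "LNN",
    "RunPercentage": "Pct", "GrayLevelVariance": "GLV", "RunVariance": "LV",
    "RunEntropy": "Entropy", "LowGrayLevelRunEmphasis": "LGL",
    "HighGrayLevelRunEmphasis": "HGL", "ShortRunLowGrayLevelEmphasis": "ShortLGL",
    "ShortRunHighGrayLevelEmphasis": "ShortHGL",
    "LongRunHighGrayLevelEmphasis": "LongHGL",
    "LongRunLowGrayLevelEmphasis": "LongLGL",
}


def glrlm_features(disc: DiscretizedVolume) -> Dict[str, float]:
    """16 run-length features averaged over the 13 directions."""
    n_vox = int(np.asarray(disc.mask).sum())
    per_dir = [_rlm_style_features(r, n_vox, "") for r in glrlm_matrices(disc)]
    return {
        name: float(np.mean([f[key] for f in per_dir]))
        for name, key in _GLRLM_MAP.items()
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_FEATURES = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

_GLSZM_MAP = {
    "SmallAreaEmphasis": "Short", "LargeAreaEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN", "GrayLevelNonUniformityNormalized": "GLNN",
    "SizeZoneNonUniformity": "LN", "SizeZoneNonUniformityNormalized": "LNN",
    "ZonePercentage": "Pct", "GrayLevelVariance": "GLV", "ZoneVariance": "LV",
    "ZoneEntropy": "Entropy", "LowGrayLevelZoneEmphasis": "LGL",
    "HighGrayLevelZoneEmphasis": "HGL", "SmallAreaLowGrayLevelEmphasis": "ShortLGL",
    "SmallAreaHighGrayLevelEmphasis": "ShortHGL",
    "LargeAreaHighGrayLevelEmphasis": "LongHGL",
    "LargeAreaLowGrayLevelEmphasis": "LongLGL",
}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Size-zone count matrix: zones are 26-connected components of equal
    gray level; columns indexed by zone size."""
    lvl, mask, ng = _check(disc)
    max_size = int(mask.sum())
    z = np.zeros((ng, max_size))
    for g in range(1, ng + 1):
        lab, n = ndimage.label(lvl == g, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            z[g - 1, s - 1] += 1
    return z


def glszm_features(disc: DiscretizedVolume) -> Dict[str, float]:
    """16 size-zone features (single matrix; no direction average)."""
    n_vox = int(np.asarray(disc.mask).sum())
    f = _rlm_style_features(glszm_matrix(disc), n_vox, "")
    return {name: f[key] for name, key in _GLSZM_MAP.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_FEATURES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

#: sentinel for Coarseness of a perfectly uniform region (infinite coarseness)
COARSENESS_MAX = 1e6


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts ``n_i`` and summed absolute differences
    ``s_i`` between each voxel's level and its 26-neighbourhood mean."""
    lvl, mask, ng = _check(disc)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = (lvl * mask).astype(float)
    nb_sum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    n = np.zeros(ng)
    s = np.zeros(ng)
    mean_nb = np.zeros(lvl.shape)
    mean_nb[valid] = nb_sum[valid] / nb_cnt[valid]
    diffs = np.abs(lvl - mean_nb)
    np.add.at(n, lvl[valid] - 1, 1.0)
    np.add.at(s, lvl[valid] - 1, diffs[valid])
    return n, s


def ngtdm_features(disc: DiscretizedVolume) -> Dict[str, float]:
    n, s = ngtdm_table(disc)
    ntot = n.sum()
    if ntot == 0:
        raise DegenerateInputError("no voxel has an in-mask neighbour")
    p = n / ntot
    ng = len(n)
    i = np.arange(1, ng + 1).astype(float)
    present = p > 0
    ngp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = COARSENESS_MAX if ps == 0 else min(1.0 / ps, COARSENESS_MAX)

    if ngp <= 1:
        contrast = 0.0
    else:
        pij = np.outer(p, p) * (i[:, None] - i[None, :]) ** 2
        contrast = float(pij.sum() / (ngp * (ngp - 1)) * (s.sum() / ntot))

    ipj = np.abs(i[:, None] * p[:, None] - i[None, :] * p[None, :])
    both = np.outer(present, present)
    denom_b = float(ipj[both].sum())
    busyness = 0.0 if denom_b == 0 else ps / denom_b

    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.abs(i[:, None] - i[None, :]) * (
            np.outer(p, np.ones(ng)) * s[:, None] + np.outer(np.ones(ng), p) * s[None, :]
        )
        den = np.outer(p, np.ones(ng)) + np.outer(np.ones(ng), p)
        term = np.where(both & (den > 0), num / np.where(den > 0, den, 1.0), 0.0)
    complexity = float(term.sum() / ntot)

    ssum = float(s.sum())
    if ssum == 0:
        strength = 0.0
    else:
        st = np.outer(p, np.ones(ng)) + np.outer(np.ones(ng), p)
        st = st * (i[:, None] - i[None, :]) ** 2
        strength = float(st[both].sum() / ssum)

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_FEATURES = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

_GLDM_MAP = {
    "SmallDependenceEmphasis": "Short", "LargeDependenceEmphasis": "Long",
    "GrayLevelNonUniformity": "GLN",
    "DependenceNonUniformity": "LN", "DependenceNonUniformityNormalized": "LNN",
    "GrayLevelVariance": "GLV", "DependenceVariance": "LV",
    "DependenceEntropy": "Entropy", "LowGrayLevelEmphasis": "LGL",
    "HighGrayLevelEmphasis": "HGL", "SmallDependenceLowGrayLevelEmphasis": "ShortLGL",
    "SmallDependenceHighGrayLevelEmphasis": "ShortHGL",
    "LargeDependenceHighGrayLevelEmphasis": "LongHGL",
    "LargeDependenceLowGrayLevelEmphasis": "LongLGL",
}


def gldm_matrix(disc: DiscretizedVolume, alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix.

    A neighbour is *dependent* when ``|level(neighbour) - level(centre)| <=
    alpha`` over the 26-neighbourhood.  A voxel with ``j`` dependent
    neighbours is tallied in column ``j``; feature formulas use dependence
    size ``j + 1`` so an isolated voxel still has size 1.
    """
    lvl, mask, ng = _check(disc)
    dep = np.zeros(lvl.shape, dtype=np.int32)
    for d in OFFSETS_26:
        nb_ok = _neighbor(mask, d, False)
        nb_lvl = _neighbor(lvl, d, 0)
        dep += (nb_ok & (np.abs(nb_lvl - lvl) <= alpha)).astype(np.int32)
    m = np.zeros((ng, 27))
    np.add.at(m, (lvl[mask] - 1, dep[mask]), 1.0)
    return m[:, : dep[mask].max() + 1]


def gldm_features(disc: DiscretizedVolume, alpha: float = 0.0) -> Dict[str, float]:
    """14 gray-level dependence features (single matrix)."""
    n_vox = int(np.asarray(disc.mask).sum())
    f = _rlm_style_features(gldm_matrix(disc, alpha), n_vox, "")
    return {name: f[key] for name, key in _GLDM_MAP.items()}
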