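"""Independent brute-force oracles for the texture families and for the
DeLong test.  Everything here is written with explicit Python loops and
direct formula transcription, deliberately sharing no code with the package
implementation."""

from __future__ import annotations

import math
from typing import Dict, List

import numpy as np

DIRS_13 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) > (0, 0, 0)
]
OFFS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices_oracle(lvl: np.ndarray, mask: np.ndarray, ng: int) -> List[np.ndarray]:
    """Exhaustive symmetric pair counting per direction (normalized)."""
    out = []
    for d in DIRS_13:
        counts = np.zeros((ng, ng))
        for v in np.argwhere(mask):
            w = tuple(v + d)
            if _inside(mask.shape, w) and mask[w]:
                counts[lvl[tuple(v)] - 1, lvl[w] - 1] += 1
                counts[lvl[w] - 1, lvl[tuple(v)] - 1] += 1
        if counts.sum():
            out.append(counts / counts.sum())
    return out


def glcm_features_oracle_one(p: np.ndarray) -> Dict[str, float]:
    """Direct double-loop transcription of the 24 co-occurrence formulas."""
    ng = p.shape[0]
    eps = np.spacing(1.0)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))

    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
            psum[i + j] += p[i][j]
    da = sum(k * pdiff[k] for k in range(ng))

    f: Dict[str, float] = {}
    f["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng))
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum((i + j + 2 - 2 * mu) ** power * p[i][j] for i in range(ng) for j in range(ng))
    f["Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if sig2 == 0:
        f["Correlation"] = 1.0
    else:
        f["Correlation"] = sum(
            (i + 1 - mu) * (j + 1 - mu) * p[i][j] for i in range(ng) for j in range(ng)
        ) / sig2
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(q * math.log2(q) for q in pdiff if q > 0)
    f["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))

    hxy = -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j] + eps)
        for i in range(ng) for j in range(ng) if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng) if px[i] * px[j] > 0
    )
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    f["Imc1"] = 0.0 if hx == 0 else (hxy - hxy1) / hx
    f["Imc2"] = 0.0 if hxy2 < hxy else math.sqrt(1 - math.exp(-2 * (hxy2 - hxy)))
    f["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["JointAverage"] = mu
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    if ng == 1:
        f["MCC"] = 1.0
    else:
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                q[i][j] = sum(
                    p[i][k] * p[j][k] / (px[i] * px[k])
                    for k in range(ng)
                    if px[i] > 0 and px[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(q)))
        f["MCC"] = math.sqrt(max(ev[-2], 0.0))
    f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    f["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * ng - 1))
    f["SumEntropy"] = -sum(q * math.log2(q) for q in psum if q > 0)
    f["SumSquares"] = sig2
    return f


def glcm_features_oracle(lvl, mask, ng) -> Dict[str, float]:
    mats = glcm_matrices_oracle(lvl, mask, ng)
    if not mats:
        mats = [np.ones((1, 1))]
    per = [glcm_features_oracle_one(p) for p in mats]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


# ---------------------------------------------------------------------------
# run-length-shaped feature formulas (shared by GLRLM/GLSZM/GLDM oracles)
# ---------------------------------------------------------------------------

def rlm_features_oracle(r: np.ndarray, n_voxels: int) -> Dict[str, float]:
    nr = r.sum()
    ng, nl = r.shape
    p = r / nr
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(nl))
    f = {}
    f["Short"] = sum(p[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f["Long"] = sum(p[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl))
    f["GLN"] = sum(sum(r[i]) ** 2 for i in range(ng)) / nr
    f["GLNN"] = sum(sum(p[i]) ** 2 for i in range(ng))
    f["LN"] = sum(sum(r[i][j] for i in range(ng)) ** 2 for j in range(nl)) / nr
    f["LNN"] = sum(sum(p[i][j] for i in range(ng)) ** 2 for j in range(nl))
    f["Pct"] = nr / n_voxels
    f["GLV"] = sum(p[i][j] * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(nl))
    f["LV"] = sum(p[i][j] * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(nl))
    f["Entropy"] = -sum(
        p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(nl) if p[i][j] > 0
    )
    f["LGL"] = sum(p[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f["HGL"] = sum(p[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl))
    f["ShortLGL"] = sum(
        p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nl)
    )
    f["ShortHGL"] = sum(
        p[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    f["LongHGL"] = sum(
        p[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    f["LongLGL"] = sum(
        p[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    )
    return f


# ---------------------------------------------------------------------------
# GLRLM: voxel-by-voxel run scan
# ---------------------------------------------------------------------------

def glrlm_matrices_oracle(lvl, mask, ng) -> List[np.ndarray]:
    max_len = max(lvl.shape)
    out = []
    for d in DIRS_13:
        r = np.zeros((ng, max_len))
        for v in np.argwhere(mask):
            prev = tuple(v - d)
            if _inside(mask.shape, prev) and mask[prev] and lvl[prev] == lvl[tuple(v)]:
                continue  # not a run start
            length = 1
            cur = tuple(v)
            while True:
                nxt = tuple(np.array(cur) + d)
                if _inside(mask.shape, nxt) and mask[nxt] and lvl[nxt] == lvl[cur]:
                    length += 1
                    cur = nxt
                else:
                    break
            r[lvl[tuple(v)] - 1, length - 1] += 1
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# GLSZM: stack-based flood fill
# ---------------------------------------------------------------------------

def glszm_matrix_oracle(lvl, mask, ng) -> np.ndarray:
    max_size = int(mask.sum())
    z = np.zeros((ng, max_size))
    seen = np.zeros(mask.shape, dtype=bool)
    for v in np.argwhere(mask):
        v = tuple(v)
        if seen[v]:
            continue
        g = lvl[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in OFFS_26:
                w = tuple(np.array(cur) + d)
                if _inside(mask.shape, w) and mask[w] and not seen[w] and lvl[w] == g:
                    seen[w] = True
                    stack.append(w)
        z[g - 1, size - 1] += 1
    return z


# ---------------------------------------------------------------------------
# NGTDM: per-voxel neighbourhood means
# ---------------------------------------------------------------------------

def ngtdm_features_oracle(lvl, mask, ng) -> Dict[str, float]:
    n = [0.0] * ng
    s = [0.0] * ng
    for v in np.argwhere(mask):
        v = tuple(v)
        nb = [
            lvl[tuple(np.array(v) + d)]
            for d in OFFS_26
            if _inside(mask.shape, tuple(np.array(v) + d)) and mask[tuple(np.array(v) + d)]
        ]
        if not nb:
            continue
        g = lvl[v]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nb) / len(nb))
    ntot = sum(n)
    p = [q / ntot for q in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(ng))

    coarse = 1e6 if ps == 0 else min(1.0 / ps, 1e6)
    if ngp <= 1:
        contrast = 0.0
    else:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
            / (ngp * (ngp - 1))
            * (sum(s) / ntot)
        )
    denb = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    busy = 0.0 if denb == 0 else ps / denb
    comp = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in present for j in present
    ) / ntot
    ssum = sum(s)
    strength = (
        0.0 if ssum == 0
        else sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
    )
    return {
        "Busyness": busy, "Coarseness": coarse, "Complexity": comp,
        "Contrast": contrast, "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM: per-voxel dependence counting
# ---------------------------------------------------------------------------

def gldm_matrix_oracle(lvl, mask, ng, alpha=0.0) -> np.ndarray:
    deps = {}
    max_dep = 0
    for v in np.argwhere(mask):
        v = tuple(v)
        dep = 0
        for d in OFFS_26:
            w = tuple(np.array(v) + d)
            if _inside(mask.shape, w) and mask[w] and abs(int(lvl[w]) - int(lvl[v])) <= alpha:
                dep += 1
        deps[v] = dep
        max_dep = max(max_dep, dep)
    m = np.zeros((ng, max_dep + 1))
    for v, dep in deps.items():
        m[lvl[v] - 1, dep] += 1
    return m


# ---------------------------------------------------------------------------
# DeLong bootstrap oracle
# ---------------------------------------------------------------------------

def bootstrap_auc_diff_p(scores_a, scores_b, y, n_boot=100_000, seed=0):
    """Stratified case-resampling bootstrap of the paired AUC difference;
    two-sided normal p using the bootstrap SD of the difference."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)

    def auc_pairs(sp, sn):
        # sp: (B, m), sn: (B, n) -> per-replicate pairwise AUC
        gt = (sp[:, :, None] > sn[:, None, :]).mean(axis=(1, 2))
        eq = (sp[:, :, None] == sn[:, None, :]).mean(axis=(1, 2))
        return gt + 0.5 * eq

    diffs = np.empty(n_boot)
    chunk = 5000
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        ip = rng.integers(0, len(pos), size=(b, len(pos)))
        ineg = rng.integers(0, len(neg), size=(b, len(neg)))
        pa, na = scores_a[pos][ip], scores_a[neg][ineg]
        pb, nb = scores_b[pos][ip], scores_b[neg][ineg]
        diffs[start:start + b] = auc_pairs(pa, na) - auc_pairs(pb, nb)

    # observed difference
    obs = (
        auc_pairs(scores_a[pos][None, :], scores_a[neg][None, :])
        - auc_pairs(scores_b[pos][None, :], scores_b[neg][None, :])
    )[0]
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if obs == 0 else 0.0
    from scipy.stats import norm

    return float(2 * norm.sf(abs(obs) / sd))
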