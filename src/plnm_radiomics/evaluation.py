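"""ROC analysis: AUC (Mann-Whitney with midranks), DeLong variance and
confidence intervals, the paired DeLong test between two models scored on
the same cases, operating-point metrics and the two-arm comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult", "DelongResult", "auc", "delong_ci", "delong_paired_test",
    "operating_point_metrics", "compare_models",
]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    curve: Optional[Tuple[np.ndarray, np.ndarray]] = field(default=None, repr=False)


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covariance: float
    z: float
    p: float


def _check_labels(y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes coded 0/1")
    return np.flatnonzero(y == 1), np.flatnonzero(y == 0)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components (V10 per positive, V01 per negative)
    computed with midranks, so ties contribute 1/2."""
    pos_idx, neg_idx = _check_labels(y)
    pos, neg = scores[pos_idx], scores[neg_idx]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = v10.mean()  # Mann-Whitney AUC
    return a, v10, v01


def auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Mann-Whitney AUC estimator; ties count half."""
    a, _, _ = _delong_components(np.asarray(scores, dtype=float), np.asarray(y))
    return float(a)


def delong_variance(scores: Sequence[float], y: Sequence[int]) -> float:
    a, v10, v01 = _delong_components(np.asarray(scores, dtype=float), np.asarray(y))
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(
    scores: Sequence[float],
    y: Sequence[int],
    level: float = 0.95,
    threshold: Optional[float] = None,
) -> RocResult:
    """AUC with DeLong normal-approximation CI, truncated to [0, 1].

    If ``threshold`` is given, the operating-point metrics at that threshold
    are filled in as well.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos_idx, neg_idx = _check_labels(y)
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("each class needs at least 2 members for a CI")
    a, v10, v01 = _delong_components(scores, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    res = RocResult(
        auc=float(a),
        ci_low=float(max(a - half, 0.0)),
        ci_high=float(min(a + half, 1.0)),
        variance=float(var),
    )
    if threshold is not None:
        acc, sens, spec = operating_point_metrics(scores, y, threshold)
        res.accuracy, res.sensitivity, res.specificity = acc, sens, spec
    return res


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    y: Sequence[int],
) -> DelongResult:
    """Paired DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be over the same cases in the same order.  The
    two-sided p-value uses the normal reference; identical scores give
    z = 0, p = 1; swapping the models negates z and keeps p.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y).astype(int)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(y):
        raise ValueError("score vectors and labels must have equal length")
    a1, v10a, v01a = _delong_components(scores_a, y)
    a2, v10b, v01b = _delong_components(scores_b, y)
    m, n = len(v10a), len(v01a)
    cov10 = np.cov(v10a, v10b, ddof=1)[0, 1] if m > 1 else 0.0
    cov01 = np.cov(v01a, v01b, ddof=1)[0, 1] if n > 1 else 0.0
    var_a = (v10a.var(ddof=1) / m + v01a.var(ddof=1) / n) if min(m, n) > 1 else 0.0
    var_b = (v10b.var(ddof=1) / m + v01b.var(ddof=1) / n) if min(m, n) > 1 else 0.0
    cov = cov10 / m + cov01 / n
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if a1 == a2 else 0.0
    else:
        z = (a1 - a2) / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(
        auc_a=float(a1), auc_b=float(a2),
        var_a=float(var_a), var_b=float(var_b), covariance=float(cov),
        z=float(z), p=float(p),
    )


def operating_point_metrics(
    scores: Sequence[float],
    y: Sequence[int],
    threshold: float,
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) calling positive at
    ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return float(acc), float(sens), float(spec)


def compare_models(
    model_a,
    model_b,
    cohorts: Dict[str, Tuple[pd.DataFrame, Sequence[int]]],
    splits: Sequence[str] = ("train", "internal", "external"),
) -> pd.DataFrame:
    """Two-arm performance report, one row per (split, arm).

    ``cohorts`` maps split name to ``(feature table, labels)``.  Columns:
    split, arm, auc, ci_low, ci_high, accuracy, sensitivity, specificity,
    delong_p (the paired test between the two arms on that split).
    """
    from .modeling import predict_scores

    rows = []
    for split in splits:
        if split not in cohorts:
            raise KeyError(f"missing split {split!r}")
        X, y = cohorts[split]
        sa = predict_scores(model_a, X)
        sb = predict_scores(model_b, X)
        test = delong_paired_test(sa, sb, y)
        for model, scores in ((model_a, sa), (model_b, sb)):
            res = delong_ci(scores, y, threshold=model.threshold)
            rows.append(
                {
                    "split": split,
                    "arm": model.arm,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "accuracy": res.accuracy,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "delong_p": test.p,
                }
            )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Table-style text rendering of :func:`compare_models` output."""
    lines = [
        f"{'split':<10}{'arm':<22}{'AUC [95% CI]':<28}"
        f"{'Acc':>7}{'Sens':>7}{'Spec':>7}{'DeLong p':>10}"
    ]
    for _, r in report.iterrows():
        lines.append(
            f"{r['split']:<10}{r['arm']:<22}"
            f"{r['auc']:.4f} [{r['ci_low']:.4f}-{r['ci_high']:.4f}]    "
            f"{r['accuracy']:>6.3f}{r['sensitivity']:>7.3f}{r['specificity']:>7.3f}"
            f"{r['delong_p']:>10.4f}"
        )
    return "\n".join(lines)
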