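"""Three-stage feature selection and standardization.

The selection pathway for the lesion-correlation model arm is:

1. **Cross-tissue Pearson filter** — a primary-lesion feature is retained
   only when its correlation with the matching metastatic-node feature,
   across PLNM-positive training cases, exceeds 0.9 in absolute value.  The
   rationale: node tissue grows from cells shed by the primary lesion, so
   lesion features that covary with node features plausibly carry the
   metastatic signature.
2. **Two-sample t test** per feature against the PLNM label (Welch by
   default), retaining p < alpha.
3. **LASSO** — an L1-penalized logistic model, penalty chosen by repeated
   stratified cross-validation; features with non-zero coefficients survive.

The lesion model arm skips stage 1.  All statistics are learned from
training rows only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

__all__ = [
    "SelectionTrace", "Standardizer", "cross_correlation_filter",
    "ttest_filter", "fit_standardizer", "lasso_select", "pair_key",
]


@dataclass
class Standardizer:
    """Per-feature mean/sd learned on training rows (zero-variance features
    are dropped with a warning)."""

    mean: pd.Series
    sd: pd.Series

    @property
    def features(self) -> List[str]:
        return list(self.mean.index)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.features] - self.mean) / self.sd

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z[self.features] * self.sd + self.mean


def fit_standardizer(X_train: pd.DataFrame) -> Standardizer:
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(sd.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}...",
            stacklevel=2,
        )
    return Standardizer(mean=mean[keep], sd=sd[keep])


def apply_standardizer(std: Standardizer, X: pd.DataFrame) -> pd.DataFrame:
    return std.transform(X)


@dataclass
class SelectionTrace:
    """Features surviving each stage, with final LASSO weights."""

    stages: Dict[str, List[str]] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)
    thresholds: Dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, retained: Sequence[str]) -> None:
        self.stages[stage] = list(retained)

    @property
    def final(self) -> List[str]:
        return next(reversed(self.stages.values()), [])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"stages": self.stages, "weights": self.weights, "thresholds": self.thresholds},
                fh, indent=2,
            )

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.weights.items(), key=lambda kv: -abs(kv[1])),
            columns=["feature", "weight"],
        )


# ---------------------------------------------------------------------------
# Stage 1: cross-tissue Pearson filter
# ---------------------------------------------------------------------------

def pair_key(name: str) -> str:
    """Tissue-agnostic pairing key so lesion and node feature columns match
    one-to-one ('T2_tumor_X' pairs 'T2_node_X'; identical names pair as-is)."""
    return name.replace("_tumor_", "_roi_").replace("_node_", "_roi_")


def cross_correlation_filter(
    lesion_pos: pd.DataFrame,
    node_pos: pd.DataFrame,
    threshold: float = 0.9,
    mode: str = "paired",
    use_abs: bool = True,
) -> List[str]:
    """Lesion features whose Pearson r with node features exceeds ``threshold``.

    ``mode='paired'`` correlates each lesion feature with its same-named node
    feature; ``mode='any'`` retains a lesion feature when *any* node feature
    correlates beyond the threshold.  Correlations are computed across
    PLNM-positive cases (the only cases with node tissue); strict inequality;
    absolute value by default (``use_abs=False`` for signed r > threshold).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("paired", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(lesion_pos) != len(node_pos) or not lesion_pos.index.equals(node_pos.index):
        raise ValueError("lesion and node tables must be indexed by the same positive cases")
    if len(lesion_pos) < 3:
        raise ValueError("need at least 3 positive cases for correlation")

    L = lesion_pos.to_numpy(dtype=float)
    N = node_pos.to_numpy(dtype=float)
    Lc = L - L.mean(axis=0)
    Nc = N - N.mean(axis=0)
    Ls = Lc.std(axis=0)
    Ns = Nc.std(axis=0)

    def _score(r: np.ndarray) -> np.ndarray:
        return np.abs(r) if use_abs else r

    retained: List[str] = []
    if mode == "paired":
        node_by_key = {pair_key(c): j for j, c in enumerate(node_pos.columns)}
        for i, col in enumerate(lesion_pos.columns):
            j = node_by_key.get(pair_key(col))
            if j is None:
                continue
            denom = Ls[i] * Ns[j]
            if denom == 0:
                continue
            r = (Lc[:, i] * Nc[:, j]).mean() / denom
            if _score(np.array(r)) > threshold:
                retained.append(col)
    else:  # any node feature
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (Lc.T @ Nc) / len(L) / np.outer(Ls, Ns)
        R = np.nan_to_num(R, nan=0.0, posinf=0.0, neginf=0.0)
        best = _score(R).max(axis=1)
        retained = [c for c, s in zip(lesion_pos.columns, best) if s > threshold]
    return retained


# ---------------------------------------------------------------------------
# Stage 2: per-feature t test
# ---------------------------------------------------------------------------

def ttest_filter(
    X: pd.DataFrame,
    y: Sequence[int],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> List[str]:
    """Features whose two-sample t test (Welch by default) gives p < alpha.

    Features that are constant within both groups have an undefined t
    statistic and are dropped.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    a = X.to_numpy(dtype=float)[y == 1]
    b = X.to_numpy(dtype=float)[y == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    p = np.where(np.isfinite(p), p, 1.0)
    return [c for c, pv in zip(X.columns, p) if pv < alpha]


# ---------------------------------------------------------------------------
# Stage 3: LASSO
# ---------------------------------------------------------------------------

def lasso_select(
    X: pd.DataFrame,
    y: Sequence[int],
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    Cs: Optional[Sequence[float]] = None,
    model: str = "logistic",
    alpha: Optional[float] = None,
    tol: float = 1e-7,
) -> tuple[List[str], Dict[str, float]]:
    """L1-penalized selection on standardized features.

    ``model='logistic'`` (default): penalty strength chosen to minimise mean
    binomial deviance over repeated stratified CV; ties on the CV curve break
    toward the stronger penalty (sparser model).  ``model='linear'`` fits a
    plain LASSO at a fixed ``alpha`` (used for closed-form checks).
    Returns the retained feature names and their coefficients.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2 and model == "logistic":
        raise ValueError("degenerate labels")
    Xv = X.to_numpy(dtype=float)

    if model == "linear":
        if alpha is None:
            raise ValueError("linear variant requires an explicit alpha")
        las = Lasso(alpha=alpha, fit_intercept=True, tol=tol)
        las.fit(Xv, y)
        coefs = las.coef_
    elif model == "logistic":
        if Cs is None:
            Cs = np.logspace(-2.5, 1.5, 25)
        cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
        folds = list(cv.split(Xv, y))
        mean_dev = []
        for C in Cs:
            devs = []
            for tr, va in folds:
                clf = LogisticRegression(
                    l1_ratio=1.0, C=C, solver="liblinear", tol=tol,
                    max_iter=2000, random_state=seed,
                )
                clf.fit(Xv[tr], y[tr])
                prob = np.clip(clf.predict_proba(Xv[va])[:, 1], 1e-12, 1 - 1e-12)
                devs.append(-2.0 * np.mean(y[va] * np.log(prob) + (1 - y[va]) * np.log(1 - prob)))
            mean_dev.append(np.mean(devs))
        best = int(np.argmin(mean_dev))  # Cs ascending: first minimum = sparsest
        clf = LogisticRegression(
            l1_ratio=1.0, C=Cs[best], solver="liblinear", tol=tol,
            max_iter=5000, random_state=seed,
        )
        clf.fit(Xv, y)
        coefs = clf.coef_.ravel()
    else:
        raise ValueError(f"unknown model {model!r}")

    retained = [c for c, w in zip(X.columns, coefs) if w != 0.0]
    weights = {c: float(w) for c, w in zip(X.columns, coefs) if w != 0.0}
    return retained, weights


# ---------------------------------------------------------------------------
# Full pathway
# ---------------------------------------------------------------------------

def select_features(
    lesion_train: pd.DataFrame,
    y_train: Sequence[int],
    node_train_pos: Optional[pd.DataFrame] = None,
    use_correlation_filter: bool = False,
    threshold: float = 0.9,
    mode: str = "paired",
    alpha: float = 0.05,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    equal_var: bool = False,
) -> tuple[SelectionTrace, Standardizer]:
    """Run the (optional correlation filter) -> t test -> LASSO pathway.

    Standardization is fit on the training rows first; the correlation filter
    uses the positive training cases only.  Retained sets are nested across
    stages by construction.
    """
    y = np.asarray(y_train)
    trace = SelectionTrace(thresholds={"correlation": threshold, "alpha": alpha})
    std = fit_standardizer(lesion_train)
    Z = std.transform(lesion_train)
    cols = list(Z.columns)
    trace.record("extracted", cols)

    if use_correlation_filter:
        if node_train_pos is None:
            raise ValueError("correlation arm requires node features for positive cases")
        pos_ids = lesion_train.index[y == 1]
        retained = cross_correlation_filter(
            Z.loc[pos_ids], node_train_pos.loc[pos_ids], threshold=threshold, mode=mode
        )
        trace.record("correlation", retained)
        Z = Z[retained]

    retained_t = ttest_filter(Z, y, alpha=alpha, equal_var=equal_var)
    trace.record("ttest", retained_t)
    Z = Z[retained_t]

    if Z.shape[1] == 0:
        trace.record("lasso", [])
        return trace, std
    retained_l, weights = lasso_select(Z, y, n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    trace.record("lasso", retained_l)
    trace.weights = weights
    return trace, std
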