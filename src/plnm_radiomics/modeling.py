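"""Class rebalancing, SVM training with repeated stratified CV, and scoring.

Two model arms share this machinery: the *lesion* arm (features selected by
t test + LASSO only) and the *lesion-correlation* arm (cross-tissue Pearson
filter first).  Training-set imbalance (~35% PLNM-positive) is handled by
SMOTE; to avoid optimistic bias the oversampling happens inside each
training fold, never on validation folds, and the decision threshold is
fixed from training data only (Youden's J).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .selection import SelectionTrace, Standardizer, select_features

__all__ = ["TrainedModel", "smote_oversample", "train_svm_cv", "predict_scores", "train_arm"]


def smote_oversample(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic sample is a convex combination ``x + lam * (nn - x)`` of a
    minority sample and one of its ``k`` nearest minority neighbours,
    ``lam ~ U[0, 1)``.  Classes are balanced exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects binary labels")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X.copy(), y.copy()
    Xmin = X[y == minority]
    if len(Xmin) < 2:
        raise ValueError("minority class must have at least 2 members")
    k_eff = min(k, len(Xmin) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), size=n_needed)
    pick = rng.integers(0, k_eff, size=n_needed)
    lam = rng.random(size=n_needed)
    partners = Xmin[neigh[base, pick]]
    synth = Xmin[base] + lam[:, None] * (partners - Xmin[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def _default_grid(X: np.ndarray) -> List[Dict[str, float]]:
    """RBF grid: C in {0.1,1,10,100}, gamma = scale heuristic x {0.1,1,10}."""
    var = float(X.var())
    g0 = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return [
        {"kernel": "rbf", "C": C, "gamma": g0 * gf}
        for C in (0.1, 1.0, 10.0, 100.0)
        for gf in (0.1, 1.0, 10.0)
    ]


@dataclass
class TrainedModel:
    """A fitted arm: standardizer + retained features + SVM + threshold."""

    arm: str
    standardizer: Standardizer
    features: List[str]
    svm: SVC
    params: Dict[str, float]
    threshold: float
    cv_aucs: List[float] = field(default_factory=list)
    trace: Optional[SelectionTrace] = None

    @property
    def cv_auc(self) -> float:
        return float(np.mean(self.cv_aucs)) if self.cv_aucs else float("nan")


def youden_threshold(scores: np.ndarray, y: Sequence[int]) -> float:
    """Score threshold maximising sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(y, scores)
    return float(thr[np.argmax(tpr - fpr)])


def train_svm_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    n_folds: int = 5,
    n_repeats: int = 5,
    kernel_grid: Optional[List[Dict[str, float]]] = None,
    seed: int = 0,
    arm: str = "lesion",
    standardizer: Optional[Standardizer] = None,
    trace: Optional[SelectionTrace] = None,
) -> TrainedModel:
    """Grid-search an SVM by repeated stratified CV with in-fold SMOTE.

    Hyperparameters maximise the mean held-out-fold AUC; ties break toward
    the first (smallest-C) grid entry.  The final model is refit on all
    training rows (SMOTE-balanced); the decision threshold is Youden's J on
    the original (non-synthetic) training rows.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    Xv = X.to_numpy(dtype=float)
    grid = kernel_grid if kernel_grid is not None else _default_grid(Xv)
    cv = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    folds = list(cv.split(Xv, y))

    fold_aucs = np.zeros((len(grid), len(folds)))
    for fi, (tr, va) in enumerate(folds):
        Xb, yb = smote_oversample(Xv[tr], y[tr], seed=seed + 1000 + fi)
        for gi, params in enumerate(grid):
            clf = SVC(**params)
            clf.fit(Xb, yb)
            fold_aucs[gi, fi] = roc_auc_score(y[va], clf.decision_function(Xv[va]))
    mean_aucs = fold_aucs.mean(axis=1)
    best = int(np.argmax(mean_aucs))

    Xb, yb = smote_oversample(Xv, y, seed=seed + 999)
    final = SVC(**grid[best])
    final.fit(Xb, yb)
    thr = youden_threshold(final.decision_function(Xv), y)
    return TrainedModel(
        arm=arm,
        standardizer=standardizer,
        features=list(X.columns),
        svm=final,
        params=dict(grid[best]),
        threshold=thr,
        cv_aucs=list(fold_aucs[best]),
        trace=trace,
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Monotone decision scores (larger = more PLNM-like) for any table
    containing the model's retained features."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise KeyError(f"missing features: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if model.standardizer is not None:
        Z = model.standardizer.transform(X[model.standardizer.features])
        Z = Z[model.features]
    else:
        Z = X[model.features]
    return model.svm.decision_function(Z.to_numpy(dtype=float))


def train_arm(
    lesion_train: pd.DataFrame,
    y_train: Sequence[int],
    arm: str = "lesion",
    node_train_pos: Optional[pd.DataFrame] = None,
    threshold: float = 0.9,
    mode: str = "paired",
    alpha: float = 0.05,
    n_folds: int = 5,
    n_repeats: int = 5,
    kernel_grid: Optional[List[Dict[str, float]]] = None,
    seed: int = 0,
) -> TrainedModel:
    """Selection pathway + SVM for one arm ('lesion' or 'lesion-correlation')."""
    if arm not in ("lesion", "lesion-correlation"):
        raise ValueError(f"unknown arm {arm!r}")
    trace, std = select_features(
        lesion_train,
        y_train,
        node_train_pos=node_train_pos,
        use_correlation_filter=(arm == "lesion-correlation"),
        threshold=threshold,
        mode=mode,
        alpha=alpha,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )
    retained = trace.final
    if not retained:
        raise RuntimeError(f"{arm}: no features survived selection")
    Z = std.transform(lesion_train)[retained]
    return train_svm_cv(
        Z, y_train, n_folds=n_folds, n_repeats=n_repeats,
        kernel_grid=kernel_grid, seed=seed, arm=arm,
        standardizer=std, trace=trace,
    )
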