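"""Cross-validated linear-discriminant classification of patient groups.

The six length-stratified features (FN and mean FA for short, middle and
long connections) are used to separate the two patient groups. The
classifier is a Fisher linear discriminant: decision scores are
``x' S_pooled^{-1} (mu_pos - mu_neg)`` with a small ridge on the pooled
within-class covariance for numerical stability. Discrimination is
reported as ROC AUC per stratified cross-validation fold, then averaged
(mean +/- SD across folds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .datamodel import ValidationError

logger = logging.getLogger(__name__)

RIDGE_FRACTION = 1e-6  # ridge = RIDGE_FRACTION * trace(S_pooled) on the diagonal


@dataclass
class CvRocResult:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    k: int
    seed: int
    feature_names: tuple[str, ...]
    positive_label: str
    roc_curves: list[pd.DataFrame] = field(default_factory=list)  # fpr/tpr per fold
    pooled_auc: float | None = None


def _fisher_scores(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Decision scores of a ridge-stabilized Fisher discriminant."""
    mu1 = X_train[y_train == 1].mean(axis=0)
    mu0 = X_train[y_train == 0].mean(axis=0)
    n1, n0 = (y_train == 1).sum(), (y_train == 0).sum()
    s1 = np.cov(X_train[y_train == 1], rowvar=False, ddof=1)
    s0 = np.cov(X_train[y_train == 0], rowvar=False, ddof=1)
    S = ((n1 - 1) * np.atleast_2d(s1) + (n0 - 1) * np.atleast_2d(s0)) / (n1 + n0 - 2)
    ridge = RIDGE_FRACTION * max(np.trace(S), 1e-30)
    w = np.linalg.solve(S + ridge * np.eye(S.shape[0]), mu1 - mu0)
    return X_test @ w


def cv_lda_roc(
    features: pd.DataFrame,
    labels,
    k: int = 5,
    seed: int = 0,
    positive_label: str | None = None,
    standardize: bool = True,
    pooled: bool = False,
) -> CvRocResult:
    """Stratified k-fold ROC AUC of a Fisher linear discriminant.

    Per fold: the discriminant is fitted on the training subjects (features
    standardized by training-fold mean/SD), decision scores are computed on
    the held-out fold and the fold AUC comes from score ranks. Features
    constant within a training fold are dropped for that fold (logged).
    With ``pooled`` the held-out scores of all folds are additionally
    combined into one pooled-score AUC.
    """
    labels = np.asarray(labels, dtype=object)
    X = features.to_numpy(dtype=float)
    if X.shape[0] != labels.shape[0]:
        raise ValidationError("features and labels lengths differ")
    if not np.isfinite(X).all():
        raise ValidationError("features must be complete (no NaN/inf)")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = "RRMS" if "RRMS" in classes else classes[1]
    if positive_label not in classes:
        raise ValidationError(f"positive label {positive_label!r} not in {classes}")
    y = (labels == positive_label).astype(int)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < k:
            raise ValidationError(
                f"class {classes[cls]!r} has {cnt} members, fewer than k={k} folds"
            )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    curves: list[pd.DataFrame] = []
    pooled_scores = np.zeros(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = X[tr], X[te]
        keep = Xtr.std(axis=0) > 0
        if not keep.all():
            dropped = [features.columns[j] for j in np.flatnonzero(~keep)]
            logger.info("fold %d: dropping constant features %s", fold, dropped)
        if not keep.any():
            raise ValidationError(f"fold {fold}: all features constant in training")
        Xtr, Xte = Xtr[:, keep], Xte[:, keep]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        scores = _fisher_scores(Xtr, y[tr], Xte)
        pooled_scores[te] = scores
        fold_aucs.append(float(roc_auc_score(y[te], scores)))
        fpr, tpr, _ = roc_curve(y[te], scores)
        curves.append(pd.DataFrame({"fold": fold, "fpr": fpr, "tpr": tpr}))

    aucs = np.asarray(fold_aucs)
    return CvRocResult(
        fold_aucs=fold_aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if k > 1 else 0.0,
        k=k,
        seed=seed,
        feature_names=tuple(map(str, features.columns)),
        positive_label=positive_label,
        roc_curves=curves,
        pooled_auc=float(roc_auc_score(y, pooled_scores)) if pooled else None,
    )
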