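"""Leave-one-out classification of saccadic pursuit from spectral features.

Protocol: for every subject, a linear model (linear-kernel SVM by default,
optionally linear discriminant analysis) is fitted on all remaining subjects
— features standardized to zero mean / unit variance with training-fold
statistics, classes weighted inversely to their sizes — and the held-out
subject's signed decision value is recorded.  The pooled decision scores
yield a ROC curve; AUC is computed by the trapezoid rule and equals the
Mann-Whitney pair-counting probability U/(n1*n2).

The "optimal" operating point maximizes Youden's J (sensitivity +
specificity - 1, ties resolved toward higher sensitivity); two fixed points
report specificity at >= 80% true positives and sensitivity at <= 20% false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidParameterError

__all__ = [
    "ClassificationResult",
    "loocv_decision_scores",
    "roc_summary",
    "lda_band_classifier",
    "band_feature_indices",
]


@dataclass
class ClassificationResult:
    auc: float
    roc: np.ndarray  # rows of (fpr, tpr, threshold)
    optimal_point: tuple[float, float]  # (sensitivity, specificity)
    tpr80_point: tuple[float, float]  # sens/spec at the >=80% TPR threshold
    fpr20_point: tuple[float, float]  # sens/spec at the <=20% FPR threshold
    scores: np.ndarray


def _make_model(model: str, C: float):
    if model == "linear_svm":
        return SVC(kernel="linear", C=C, class_weight="balanced")
    if model == "lda":
        return LinearDiscriminantAnalysis()
    raise InvalidParameterError(f"unknown model {model!r}")


def loocv_decision_scores(
    features: np.ndarray,
    labels: np.ndarray,
    model: str = "linear_svm",
    C: float = 1.0,
    standardize: str = "per_fold",
) -> np.ndarray:
    """Held-out decision value per subject under leave-one-out CV.

    ``standardize`` is ``"per_fold"`` (training-fold statistics only, the
    leakage-safe default) or ``"global"`` (standardize once on everyone
    before cross-validation).
    """
    X = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise InvalidParameterError("features must be (n_subjects, n_features) matching labels")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise InvalidParameterError(f"non-finite features for subjects {np.flatnonzero(bad).tolist()}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise InvalidParameterError("need two classes with at least 2 subjects each")
    if standardize not in ("per_fold", "global"):
        raise InvalidParameterError("standardize must be 'per_fold' or 'global'")

    if standardize == "global":
        X = StandardScaler().fit_transform(X)

    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        Xtr, Xte = X[tr], X[i : i + 1]
        if standardize == "per_fold":
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = _make_model(model, C)
        clf.fit(Xtr, y[tr])
        scores[i] = float(clf.decision_function(Xte)[0])
    return scores


def roc_summary(scores: np.ndarray, labels: np.ndarray) -> ClassificationResult:
    """ROC characterization of pooled decision scores."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise InvalidParameterError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # ties toward higher sensitivity
    opt = best[np.argmax(tpr[best])]
    optimal = (float(tpr[opt]), float(1.0 - fpr[opt]))

    k80 = np.flatnonzero(tpr >= 0.80)
    tpr80 = (float(tpr[k80[0]]), float(1.0 - fpr[k80[0]])) if len(k80) else (float("nan"),) * 2
    k20 = np.flatnonzero(fpr <= 0.20)
    fpr20 = (
        (float(tpr[k20[-1]]), float(1.0 - fpr[k20[-1]])) if len(k20) else (float("nan"),) * 2
    )
    roc = np.column_stack([fpr, tpr, thr])
    return ClassificationResult(auc, roc, optimal, tpr80, fpr20, scores)


def band_feature_indices(bands=(1, 2)) -> list[int]:
    """Column indices of the Sum and Var features for the given half-Hz bands.

    Band index 1 is 1.5-2 Hz and 2 is 2-2.5 Hz in the 14-band layout, so the
    default picks the four features covering 1.5-2.5 Hz (Sum and Var each).
    """
    return [b for b in bands] + [14 + b for b in bands]


def lda_band_classifier(
    features_subset: np.ndarray, labels: np.ndarray
) -> ClassificationResult:
    """LOOCV linear-discriminant classifier on the 4-feature 1.5-2.5 Hz subset."""
    X = np.asarray(features_subset, float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise InvalidParameterError("expected exactly 4 band features per subject")
    scores = loocv_decision_scores(X, labels, model="lda")
    return roc_summary(scores, labels)
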