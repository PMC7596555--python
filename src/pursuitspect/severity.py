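"""Pairwise-comparison estimation of oculomotor severity.

Clinical severity labels (the 0-2 oculomotor subscore of an ataxia rating
scale, in half-point steps) are coarse and noisy, so instead of regressing
the score directly the estimator learns *orderings*: for every pair of
subjects with different scores, an L1-regularized logistic model is trained
to predict which one is more severe from the difference of their 28 spectral
features.  Both orderings of each pair are included (delta and -delta with
flipped label), which makes the optimal intercept zero by symmetry; the
intercept is therefore omitted.

A separate model is fitted for each subject with that subject's pairs
excluded, and the subject's severity estimate is the learned weight vector
applied to their (training-standardized) feature vector — an estimate on the
model's native linear scale, blind to the subject's own data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import InvalidParameterError

__all__ = [
    "PairwiseDataset",
    "SeverityEstimate",
    "build_pairwise",
    "fit_pairwise_model",
    "estimate_scores_loo",
    "pairwise_accuracy",
]


@dataclass
class PairwiseDataset:
    """Feature differences and more-severe indicators for unequal-score pairs."""

    deltas: np.ndarray  # (n_rows, n_features), includes both orderings
    labels: np.ndarray  # 1 if the first member of the ordering is more severe
    pairs: list[tuple[int, int]]  # subject index pairs, one entry per row

    def __len__(self) -> int:
        return len(self.labels)


def build_pairwise(
    features: np.ndarray, scores: np.ndarray, exclude_subject: int | None = None
) -> PairwiseDataset:
    """All unordered unequal-score pairs, antisymmetrically augmented.

    Pairs involving ``exclude_subject`` are dropped (leave-one-out
    construction); equal-score pairs are excluded by definition.
    """
    X = np.asarray(features, float)
    s = np.asarray(scores, float)
    if len(X) != len(s):
        raise InvalidParameterError("features and scores must align")
    idx = [i for i in range(len(s)) if i != exclude_subject]
    if len(set(s[idx])) < 2:
        raise InvalidParameterError("need at least 2 distinct scores to form pairs")
    deltas, labels, pairs = [], [], []
    for i, j in itertools.combinations(idx, 2):
        if s[i] == s[j]:
            continue
        d = X[i] - X[j]
        lab = 1 if s[i] > s[j] else 0
        deltas.append(d)
        labels.append(lab)
        pairs.append((i, j))
        deltas.append(-d)
        labels.append(1 - lab)
        pairs.append((j, i))
    return PairwiseDataset(np.asarray(deltas), np.asarray(labels), pairs)


def fit_pairwise_model(
    dataset: PairwiseDataset, l1_strength: float = 1.0, max_iter: int = 5000
) -> np.ndarray:
    """L1-penalized logistic weights on feature deltas, zero intercept.

    ``l1_strength`` follows the inverse-regularization convention (the C of
    the solver): larger means weaker penalty.
    """
    if len(dataset) == 0:
        raise InvalidParameterError("empty pairwise dataset")
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure L1 penalty
        C=l1_strength,
        solver="liblinear",
        fit_intercept=False,
        tol=1e-6,
        max_iter=max_iter,
        random_state=0,  # liblinear shuffles coordinates; pin for determinism
    )
    clf.fit(dataset.deltas, dataset.labels)
    if np.asarray(clf.n_iter_).max() >= max_iter:
        raise InvalidParameterError(
            f"pairwise logistic model failed to converge within {max_iter} iterations"
        )
    return clf.coef_.ravel().copy()


@dataclass
class SeverityEstimate:
    """Leave-one-out severity estimates and their agreement with the clinic."""

    estimates: np.ndarray  # one per subject, native linear scale
    weights: np.ndarray  # (n_subjects, n_features), the model that scored each
    pearson_r: float
    spearman_rho: float
    pairwise_acc: float


def estimate_scores_loo(
    features: np.ndarray,
    scores: np.ndarray,
    l1_strength: float = 1.0,
    standardize: bool = True,
) -> SeverityEstimate:
    """Severity estimate per subject from a model blind to that subject.

    For each subject i the pairwise model is trained on all pairs among the
    other subjects (features standardized with their statistics) and the
    estimate is the dot product of the learned weights with subject i's
    standardized features.  ``standardize=False`` applies weights to raw
    features instead.
    """
    X = np.asarray(features, float)
    s = np.asarray(scores, float)
    n = len(s)
    if n < 3:
        raise InvalidParameterError("need at least 3 subjects")
    if len(set(s)) < 2:
        raise InvalidParameterError("need at least 2 distinct scores")

    estimates = np.empty(n)
    weights = np.empty((n, X.shape[1]))
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        if standardize:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - mu) / sd
        else:
            Z = X
        ds = build_pairwise(Z, s, exclude_subject=i)
        w = fit_pairwise_model(ds, l1_strength=l1_strength)
        weights[i] = w
        estimates[i] = float(w @ Z[i])

    pr = float(stats.pearsonr(estimates, s)[0]) if np.std(estimates) > 0 else 0.0
    sr = float(stats.spearmanr(estimates, s)[0]) if np.std(estimates) > 0 else 0.0
    acc = pairwise_accuracy(estimates, s)
    return SeverityEstimate(estimates, weights, pr, sr, acc)


def pairwise_accuracy(estimates: np.ndarray, scores: np.ndarray) -> float:
    """Fraction of unequal-score pairs ordered correctly by the estimates.

    Exact ties among estimates earn half credit, so an uninformative constant
    estimator scores 0.5 rather than 0.
    """
    e = np.asarray(estimates, float)
    s = np.asarray(scores, float)
    hits = 0.0
    total = 0
    for i, j in itertools.combinations(range(len(s)), 2):
        if s[i] == s[j]:
            continue
        total += 1
        if e[i] == e[j]:
            hits += 0.5
        elif (e[i] > e[j]) == (s[i] > s[j]):
            hits += 1.0
    if total == 0:
        raise InvalidParameterError("no unequal-score pairs")
    return hits / total
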