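"""Mahalanobis-distance group separation and product-k-fold cross-validation.

For multidimensional sensor data the Mahalanobis distance

    MD(x, y) = sqrt((x - y)^T C^{-1} (x - y))

with C the covariance matrix of the analysed data is a variance-scaled
separation measure between group centroids.  Under a standard-normal
calibration MD > 1.96 corresponds to p < 0.05 and MD > 2.58 to p < 0.01
(two-sided tail mapping p = 2 (1 - Phi(MD))).

The companion cross-validation enumerates every tuple holding out exactly one
sample per group — k folds where k is the product of the group sizes — and
reports the fraction of correct predictions (the cross-validation value, CVV).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .metrics import ValidationError

#: MD thresholds for two-sided normal significance at 5% and 1%.
MD_SIG_05 = 1.96
MD_SIG_01 = 2.58

#: Default ridge scale applied to a singular covariance (x mean diagonal).
RIDGE_SCALE = 1e-6


@dataclass
class MdResult:
    pair: tuple[str, str]
    md: float
    p_value: float
    significant_05: bool
    significant_01: bool


@dataclass
class CvvReport:
    k: int
    correct: int
    total: int

    @property
    def cvv(self) -> float:
        return self.correct / self.total


def _ridge(cov: np.ndarray, scale: float = RIDGE_SCALE) -> np.ndarray:
    lam = scale * float(np.mean(np.diag(cov)))
    if lam <= 0:
        lam = scale
    return cov + lam * np.eye(cov.shape[0])


def mahalanobis_distance(
    x: np.ndarray, y: np.ndarray, covariance: np.ndarray
) -> float:
    """MD(x, y) via a Cholesky solve (no explicit matrix inverse).

    ``covariance`` must be symmetric positive definite; symmetric in (x, y);
    zero iff x == y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    n = x.shape[0]
    if y.shape != (n,) or covariance.shape != (n, n):
        raise ValidationError("x, y and covariance are dimensionally inconsistent")
    if not np.allclose(covariance, covariance.T, rtol=1e-8, atol=1e-10):
        raise ValidationError("covariance must be symmetric")
    d = x - y
    try:
        c, low = linalg.cho_factor(covariance)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite: {exc}"
        ) from exc
    q = float(d @ linalg.cho_solve((c, low), d))
    return float(np.sqrt(max(q, 0.0)))


def md_p_value(md: float) -> float:
    """Two-sided standard-normal tail: p = 2 (1 - Phi(MD))."""
    return float(2.0 * stats.norm.sf(md))


def group_md(
    values: np.ndarray,
    labels,
    pair: tuple[str, str],
    covariance: str = "total",
    ridge_scale: float = RIDGE_SCALE,
) -> MdResult:
    """Mahalanobis distance between two group centroids.

    ``covariance="total"`` (default) uses the covariance of the full analysed
    data matrix; ``"pooled"`` uses the pooled within-group covariance.  A
    singular covariance is ridge-regularized with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a, b = pair
    xa = values[labels == a]
    xb = values[labels == b]
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("both groups need at least 2 samples")
    if covariance == "total":
        cov = np.cov(values, rowvar=False)
    elif covariance == "pooled":
        groups = [values[labels == g] for g in np.unique(labels)]
        dof = sum(len(g) - 1 for g in groups)
        cov = sum((len(g) - 1) * np.cov(g, rowvar=False) for g in groups) / dof
    else:
        raise ValidationError("covariance must be 'total' or 'pooled'")
    cov = np.atleast_2d(cov)
    try:
        md = mahalanobis_distance(xa.mean(axis=0), xb.mean(axis=0), cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular covariance: applying ridge regularization", stacklevel=2
        )
        md = mahalanobis_distance(
            xa.mean(axis=0), xb.mean(axis=0), _ridge(cov, ridge_scale)
        )
    return MdResult(
        pair=(a, b),
        md=md,
        p_value=md_p_value(md),
        significant_05=md > MD_SIG_05,
        significant_01=md > MD_SIG_01,
    )


class NearestCentroid:
    """Minimal nearest-centroid classifier (default for the CVV scheme)."""

    def fit(self, X: np.ndarray, y) -> "NearestCentroid":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.centroids_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        return self.classes_[np.argmin(d, axis=1)]


def product_kfold_cvv(
    values: np.ndarray,
    labels,
    classifier_factory=None,
) -> CvvReport:
    """Cross-validation value over all one-sample-per-group holdout tuples.

    Enumerates every tuple containing exactly one sample from each group
    (k = product of group sizes tuples); for each, the classifier is trained
    on the remaining samples and the held-out tuple predicted.  CVV is the
    fraction correct over all k x (number of groups) predictions.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels.tolist()))  # stable order
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    idx_by_group = [np.flatnonzero(labels == g) for g in groups]
    if any(len(ix) == 0 for ix in idx_by_group):
        raise ValidationError("every group must be non-empty")
    if classifier_factory is None:
        classifier_factory = NearestCentroid
    n = len(labels)
    k = 1
    for ix in idx_by_group:
        k *= len(ix)
    correct = 0
    total = 0
    for tup in itertools.product(*idx_by_group):
        held = np.array(tup)
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        clf = classifier_factory()
        clf.fit(values[mask], labels[mask])
        pred = clf.predict(values[held])
        correct += int(np.sum(np.asarray(pred) == labels[held]))
        total += len(held)
    return CvvReport(k=k, correct=correct, total=total)
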