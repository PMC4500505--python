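"""eNose smell-print classification: PCA, LDA, stepwise AIC selection, CV.

The 32-channel sensor matrix is factorised by principal component analysis
and the classifier draws its predictors from the *combined* pool of raw
sensor columns and PC score columns (tags ``raw-1`` .. ``raw-32`` and
``PC-1`` ..).  Predictors are selected stepwise by the Akaike information
criterion of a linear discriminant model, and the model is validated by
leave-one-out cross-validation and by cross-site transfer (fit on one study
site, predict the other).

All fold-level fitting — normalization, PCA basis, predictor selection and
the LDA itself — is computed from training data only; held-out samples are
projected into the training basis.

Notes on the LDA
----------------
Classes share a pooled within-class covariance.  Prediction assigns the
class minimizing the Mahalanobis distance to the class mean adjusted by the
log prior; posterior class probabilities are the softmax of those
discriminant scores.  AIC uses the multinomial log-likelihood of the
posteriors with penalty 2 x (number of fitted parameters), counting g*d mean
parameters, d(d+1)/2 covariance parameters and g-1 free priors for g classes
and d predictors.  A singular pooled covariance is ridge-regularized
(lambda = 1e-6 x mean diagonal) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .metrics import ConfusionMatrix, ValidationError
from .preprocess import RangeNormalizer, SensorMatrix

RIDGE_SCALE = 1e-6
#: Relative eigenvalue floor below which a principal component is discarded.
PCA_EIGVAL_RTOL = 1e-10


# ---------------------------------------------------------------------------
# Predictor pool (raw sensors + PCA scores)
# ---------------------------------------------------------------------------

@dataclass
class PcaBasis:
    mean: np.ndarray
    components: np.ndarray        # p x q, columns are eigenvectors
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components


@dataclass
class PredictorPool:
    """Ordered union of raw sensor columns and PC score columns."""

    raw: np.ndarray
    scores: np.ndarray
    tags: list[str]
    basis: PcaBasis

    @property
    def n_samples(self) -> int:
        return self.raw.shape[0]

    def matrix(self, tags: list[str] | None = None) -> np.ndarray:
        combined = np.hstack([self.raw, self.scores])
        if tags is None:
            return combined
        index = {t: i for i, t in enumerate(self.tags)}
        try:
            cols = [index[t] for t in tags]
        except KeyError as exc:
            raise ValidationError(f"unknown predictor tag {exc}") from exc
        return combined[:, cols]

    def project(self, X_new: np.ndarray, tags: list[str] | None = None) -> np.ndarray:
        """Features for new samples in this pool's (training) basis."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        combined = np.hstack([X_new, self.basis.transform(X_new)])
        if tags is None:
            return combined
        index = {t: i for i, t in enumerate(self.tags)}
        cols = [index[t] for t in tags]
        return combined[:, cols]


def pca_scores(m: SensorMatrix | np.ndarray) -> PredictorPool:
    """PCA of the centered sensor matrix; pool = raw columns + PC scores.

    Scores are projections of centered data on the eigenvectors of the sample
    covariance, ordered by decreasing eigenvalue; components with negligible
    eigenvalue (below ``PCA_EIGVAL_RTOL`` x largest) are dropped, so the
    score count never exceeds min(samples - 1, sensors).
    """
    X = m.values if isinstance(m, SensorMatrix) else np.asarray(m, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA requires at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of centered data: eigvals of covariance are s^2 / (n - 1)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    if eigvals[0] > 0:
        keep = eigvals > PCA_EIGVAL_RTOL * eigvals[0]
    else:
        keep = np.zeros_like(eigvals, dtype=bool)
    keep &= np.arange(len(eigvals)) < min(n - 1, p)
    components = vt[keep].T
    basis = PcaBasis(mean=mean, components=components,
                     explained_variance=eigvals[keep])
    scores = Xc @ components
    tags = [f"raw-{i + 1}" for i in range(p)] + [
        f"PC-{j + 1}" for j in range(components.shape[1])
    ]
    return PredictorPool(raw=X, scores=scores, tags=tags, basis=basis)


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    selected_predictors: list[str]
    classes: list[str]
    class_means: np.ndarray            # g x d
    pooled_covariance_inverse: np.ndarray
    log_priors: np.ndarray
    ridged: bool = False

    def _scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diffs = X[:, None, :] - self.class_means[None, :, :]  # n x g x d
        quad = np.einsum("ngd,de,nge->ng", diffs,
                         self.pooled_covariance_inverse, diffs)
        return -0.5 * quad + self.log_priors[None, :]

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self._scores(X), axis=1)
        return np.array(self.classes, dtype=object)[idx]

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        s = self._scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def log_likelihood(self, X: np.ndarray, y) -> float:
        post = self.posteriors(X)
        y = np.asarray(y)
        idx = np.array([self.classes.index(lab) for lab in y])
        p = np.clip(post[np.arange(len(y)), idx], 1e-300, None)
        return float(np.log(p).sum())

    @property
    def n_parameters(self) -> int:
        g = len(self.classes)
        d = self.class_means.shape[1]
        return g * d + d * (d + 1) // 2 + (g - 1)


def _fit_lda_matrix(X: np.ndarray, y, ridge_scale: float = RIDGE_SCALE,
                    tags: list[str] | None = None) -> LdaModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, d = X.shape
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValidationError("LDA requires at least 2 classes")
    counts = np.array([np.sum(y == c) for c in classes])
    if np.any(counts < 2):
        raise ValidationError("every class needs at least 2 samples")
    if d >= n:
        raise ValidationError("predictor count must be smaller than sample count")
    means = np.array([X[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        Xc = X[y == c] - mu
        pooled += Xc.T @ Xc
    pooled /= n - len(classes)
    ridged = False
    try:
        chol = linalg.cho_factor(pooled)
    except linalg.LinAlgError:
        warnings.warn("singular pooled covariance: ridge applied", stacklevel=2)
        lam = ridge_scale * max(float(np.mean(np.diag(pooled))), ridge_scale)
        pooled = pooled + lam * np.eye(d)
        chol = linalg.cho_factor(pooled)
        ridged = True
    cov_inv = linalg.cho_solve(chol, np.eye(d))
    priors = counts / n
    return LdaModel(
        selected_predictors=list(tags) if tags is not None else
        [f"x{i}" for i in range(d)],
        classes=classes,
        class_means=means,
        pooled_covariance_inverse=cov_inv,
        log_priors=np.log(priors),
        ridged=ridged,
    )


def fit_lda(pool: PredictorPool, labels, predictors: list[str],
            ridge_scale: float = RIDGE_SCALE) -> LdaModel:
    """Fit a pooled-covariance LDA on the selected predictor tags."""
    if not predictors:
        raise ValidationError("predictor list is empty")
    X = pool.matrix(predictors)
    return _fit_lda_matrix(X, labels, ridge_scale=ridge_scale, tags=predictors)


class LdaClassifier:
    """Estimator-style wrapper (fit/predict) over plain feature matrices."""

    def __init__(self, ridge_scale: float = RIDGE_SCALE):
        self.ridge_scale = ridge_scale

    def fit(self, X, y) -> "LdaClassifier":
        self.model_ = _fit_lda_matrix(X, y, ridge_scale=self.ridge_scale)
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(X)


# ---------------------------------------------------------------------------
# Stepwise predictor selection by AIC
# ---------------------------------------------------------------------------

def _prior_only_aic(labels) -> float:
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / len(y)
    loglik = float(np.sum(counts * np.log(priors)))
    return -2.0 * loglik + 2.0 * (len(classes) - 1)


def _model_aic(pool: PredictorPool, labels, tags: list[str]) -> float:
    model = fit_lda(pool, labels, tags)
    loglik = model.log_likelihood(pool.matrix(tags), labels)
    return -2.0 * loglik + 2.0 * model.n_parameters


def stepwise_select(
    pool: PredictorPool,
    labels,
    direction: str = "forward",
    max_predictors: int | None = None,
) -> list[str]:
    """Greedy AIC-minimizing predictor selection over the combined pool.

    Forward steps add the predictor whose addition lowers AIC most (ties
    broken by pool order, i.e. lowest predictor index); with
    ``direction="both"`` a drop step follows each add.  Stops when no move
    lowers AIC.  Deterministic given the pool order.
    """
    if direction not in ("forward", "both"):
        raise ValidationError("direction must be 'forward' or 'both'")
    if not pool.tags:
        raise ValidationError("predictor pool is empty")
    y = np.asarray(labels)
    n = pool.n_samples
    g = len(set(y.tolist()))
    cap = max(1, n - g - 1)
    if max_predictors is not None:
        cap = min(cap, max_predictors)
    selected: list[str] = []
    best_aic = _prior_only_aic(y)
    improved = True
    while improved:
        improved = False
        # forward step
        if len(selected) < cap:
            best_add, best_add_aic = None, best_aic
            for tag in pool.tags:
                if tag in selected:
                    continue
                try:
                    aic = _model_aic(pool, y, selected + [tag])
                except ValidationError:
                    continue
                if aic < best_add_aic - 1e-9:
                    best_add, best_add_aic = tag, aic
            if best_add is not None:
                selected.append(best_add)
                best_aic = best_add_aic
                improved = True
        # backward step
        if direction == "both" and len(selected) > 1:
            best_drop, best_drop_aic = None, best_aic
            for tag in selected:
                trial = [t for t in selected if t != tag]
                aic = _model_aic(pool, y, trial)
                if aic < best_drop_aic - 1e-9:
                    best_drop, best_drop_aic = tag, aic
            if best_drop is not None:
                selected.remove(best_drop)
                best_aic = best_drop_aic
                improved = True
    return selected


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    confusion: ConfusionMatrix
    per_fold_predictions: list[dict]
    scheme: str
    skipped_folds: list[int] = field(default_factory=list)


def _fit_fold(train_values: np.ndarray, train_labels, selection: str,
              normalize: bool, max_predictors: int | None):
    """Fit normalization, PCA pool, selection and LDA on training data only."""
    norm = None
    X = train_values
    if normalize:
        norm = RangeNormalizer().fit(train_values)
        X = norm.transform(train_values)
    pool = pca_scores(X)
    tags = stepwise_select(pool, train_labels, direction=selection,
                           max_predictors=max_predictors)
    model = fit_lda(pool, train_labels, tags) if tags else None
    return norm, pool, tags, model


def _predict_fold(norm, pool, tags, model, train_labels, test_values):
    test_values = np.atleast_2d(np.asarray(test_values, dtype=float))
    if norm is not None:
        test_values = norm.transform(test_values, clamp=True)
    if model is None:
        # empty selection: predict the majority (highest-prior) class
        y = np.asarray(train_labels)
        classes, counts = np.unique(y, return_counts=True)
        return np.repeat(classes[np.argmax(counts)], len(test_values))
    feats = pool.project(test_values, tags)
    return model.predict(feats)


def loocv(
    values: np.ndarray,
    labels,
    selection: str = "forward",
    normalize: bool = True,
    max_predictors: int | None = None,
) -> CvReport:
    """Leave-one-out CV refitting the entire pipeline inside every fold.

    For each held-out observation the normalization, PCA basis, stepwise
    selection and LDA are recomputed on the remaining observations, and the
    held-out observation is projected into that training basis.  Folds whose
    training split loses a class entirely are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValidationError("LOOCV requires at least 3 observations")
    all_classes = sorted(set(y.tolist()))
    estimated, true, folds, skipped = [], [], [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(set(ytr.tolist())) < len(all_classes):
            warnings.warn(f"fold {i}: class vanished from training split; skipped",
                          stacklevel=2)
            skipped.append(i)
            continue
        norm, pool, tags, model = _fit_fold(values[mask], ytr, selection,
                                            normalize, max_predictors)
        pred = _predict_fold(norm, pool, tags, model, ytr, values[i])[0]
        estimated.append(pred)
        true.append(y[i])
        folds.append({"index": i, "true": y[i], "estimated": pred,
                      "selected": list(tags)})
    confusion = ConfusionMatrix.from_predictions(estimated, true, all_classes)
    return CvReport(confusion=confusion, per_fold_predictions=folds,
                    scheme="loocv", skipped_folds=skipped)


def cross_site_transfer(
    train_values: np.ndarray,
    train_labels,
    test_values: np.ndarray,
    test_labels,
    selection: str = "forward",
    normalize: bool = True,
    max_predictors: int | None = None,
) -> CvReport:
    """Fit on one site, predict the other.

    The PCA basis, predictor selection and LDA are fit on the training site
    only; test-site data are normalized with the training min/max (clamped)
    and projected into the training PCA basis before prediction.
    """
    train_values = np.asarray(train_values, dtype=float)
    test_values = np.atleast_2d(np.asarray(test_values, dtype=float))
    if train_values.shape[1] != test_values.shape[1]:
        raise ValidationError("sensor count differs between sites")
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    norm, pool, tags, model = _fit_fold(train_values, ytr, selection,
                                        normalize, max_predictors)
    preds = _predict_fold(norm, pool, tags, model, ytr, test_values)
    all_classes = sorted(set(ytr.tolist()) | set(yte.tolist()))
    confusion = ConfusionMatrix.from_predictions(list(preds), list(yte), all_classes)
    folds = [{"index": i, "true": t, "estimated": p, "selected": list(tags)}
             for i, (t, p) in enumerate(zip(yte, preds))]
    return CvReport(confusion=confusion, per_fold_predictions=folds,
                    scheme="cross_site")
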