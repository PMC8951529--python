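"""Linear discriminant analysis with a shared class covariance.

Classes are modelled as Gaussians with a common (pooled) covariance, so the
per-class discriminant score is linear in the features. The fitted model also
retains the between- and within-class scatter matrices and the generalised
eigen-directions maximising their ratio (at most ``n_classes - 1`` of them),
for diagnostics and projection. Ties in the argmax are broken by canonical
class order. A singular pooled covariance is ridge-regularised with a logged
epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class LDAModel:
    classes: np.ndarray
    means: np.ndarray  # (C, d)
    covariance: np.ndarray  # pooled, (d, d)
    priors: np.ndarray  # (C,)
    coef: np.ndarray  # (C, d) discriminant weights
    intercept: np.ndarray  # (C,)
    scalings: np.ndarray  # (d, <=C-1) scatter-ratio directions
    Sb: np.ndarray
    Sw: np.ndarray
    ridge: float


def lda_fit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> LDAModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least two rows")
    n, d = X.shape
    C = len(classes)

    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    priors = counts / n
    grand = X.mean(axis=0)

    Sw = np.zeros((d, d))
    for i, c in enumerate(classes):
        diff = X[y == c] - means[i]
        Sw += diff.T @ diff
    Sb = np.zeros((d, d))
    for i, c in enumerate(classes):
        dm = (means[i] - grand)[:, None]
        Sb += counts[i] * (dm @ dm.T)

    cov = Sw / (n - C)
    eps = ridge
    while True:
        try:
            cho = linalg.cho_factor(cov + eps * np.eye(d))
            break
        except linalg.LinAlgError:
            eps = max(eps * 10.0, 1e-10 * max(np.trace(cov) / d, 1.0))
            logger.warning("singular pooled covariance; ridge epsilon -> %g", eps)
    if eps:
        cov = cov + eps * np.eye(d)

    coef = linalg.cho_solve(cho, means.T).T  # (C, d) = Sigma^-1 mu_c
    intercept = -0.5 * np.sum(means * coef, axis=1) + np.log(priors)

    # directions maximising the between/within scatter ratio
    n_dir = min(C - 1, d)
    try:
        evals, evecs = linalg.eigh(Sb, Sw + (eps * (n - C) + 1e-12) * np.eye(d))
        order = np.argsort(evals)[::-1]
        scalings = evecs[:, order[:n_dir]]
    except linalg.LinAlgError:  # pragma: no cover - degenerate diagnostics only
        scalings = np.zeros((d, n_dir))

    return LDAModel(
        classes=classes,
        means=means,
        covariance=cov,
        priors=priors,
        coef=coef,
        intercept=intercept,
        scalings=scalings,
        Sb=Sb,
        Sw=Sw,
        ridge=eps,
    )


def lda_decision_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.coef.shape[1]:
        raise ValueError("feature dimensionality does not match the fitted model")
    return X @ model.coef.T + model.intercept


def lda_predict(model: LDAModel, X: np.ndarray, return_scores: bool = False):
    scores = lda_decision_scores(model, X)
    labels = model.classes[np.argmax(scores, axis=1)]  # first max: canonical order
    return (labels, scores) if return_scores else labels


class LDAClassifier:
    """Thin fit/predict facade over :func:`lda_fit` / :func:`lda_predict`."""

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge
        self.model_: LDAModel | None = None

    def fit(self, X, y, groups=None):
        self.model_ = lda_fit(X, y, ridge=self.ridge)
        return self

    def predict(self, X, groups=None):
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return lda_predict(self.model_, X)
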