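"""Partial least squares discriminant analysis via NIPALS.

The response is a {0,1} one-hot class matrix; X and Y are column-centred and
latent components extracted by the classic NIPALS alternation (weight, score,
loading, deflation), stopping each inner iteration when the score vector
changes by less than ``tol`` (default 1e-6) or at ``max_iter`` (default 500).
With as many components as the rank of X, the fitted values coincide with
ordinary least squares.

The decision rule assigns the class of the maximum predicted output; when no
output is positive the argmax is still taken and the event counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PLSDAModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # W (d, A)
    x_scores: np.ndarray  # T (n, A)
    x_loadings: np.ndarray  # P (d, A)
    y_loadings: np.ndarray  # Q (m, A)
    coef: np.ndarray  # B (d, m): centred X -> centred Y
    kept_columns: np.ndarray  # indices of non-constant X columns
    n_iterations: list[int]
    converged: list[bool]


def plsda_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PLSDAModel:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d_all = X.shape

    x_mean_all = X.mean(axis=0)
    Xc_all = X - x_mean_all
    kept = np.flatnonzero(Xc_all.std(axis=0) > 0)
    if len(kept) < d_all:
        logger.warning("dropping %d zero-variance columns", d_all - len(kept))
    Xc = Xc_all[:, kept]
    d = Xc.shape[1]
    if n_components > d:
        raise ValueError("n_components exceeds the number of usable features")
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W = np.zeros((d, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((d, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    n_iters: list[int] = []
    conv: list[bool] = []

    for a in range(n_components):
        # start from the Y column with the largest remaining variance
        u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
        if np.allclose(u, 0):
            logger.warning("response fully deflated after %d components", a)
            W, T, P, Q = W[:, :a], T[:, :a], P[:, :a], Q[:, :a]
            n_components = a
            break
        t_old = np.zeros(n)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = Xc.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = Xc @ w
            q = Yc.T @ t / (t @ t)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1e-300):
                converged = True
                break
            t_old = t
        if not converged:
            warnings.warn(
                f"NIPALS component {a + 1} did not converge in {max_iter} iterations",
                stacklevel=2,
            )
        p = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        Yc = Yc - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p, q
        n_iters.append(it)
        conv.append(converged)

    # B maps centred X (kept columns) to centred Y
    PtW = P.T @ W
    B = W @ np.linalg.solve(PtW, Q.T) if n_components else np.zeros((d, Y.shape[1]))
    return PLSDAModel(
        n_components=n_components,
        x_mean=x_mean_all,
        y_mean=y_mean,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        coef=B,
        kept_columns=kept,
        n_iterations=n_iters,
        converged=conv,
    )


def plsda_decision_values(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.x_mean):
        raise ValueError("feature dimensionality does not match the fitted model")
    Xc = (X - model.x_mean)[:, model.kept_columns]
    return Xc @ model.coef + model.y_mean


def plsda_predict(model: PLSDAModel, X: np.ndarray):
    """Return (labels, continuous outputs, n_no_positive).

    ``labels`` are column indices of the one-hot response; ``n_no_positive``
    counts rows where no output was positive (argmax fallback applied).
    """
    Yhat = plsda_decision_values(model, X)
    labels = np.argmax(Yhat, axis=1)
    n_no_positive = int(np.sum(Yhat.max(axis=1) <= 0.0))
    return labels, Yhat, n_no_positive


def one_hot(y: np.ndarray, n_classes: int = 3) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


class PLSDAClassifier:
    """One-hot {0,1} coding, NIPALS fit, max-positive decision rule."""

    def __init__(
        self,
        n_components: int = 2,
        n_classes: int = 3,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.n_components = n_components
        self.n_classes = n_classes
        self.tol = tol
        self.max_iter = max_iter
        self.model_: PLSDAModel | None = None
        self.no_positive_count_ = 0

    def fit(self, X, y, groups=None):
        Y = one_hot(y, self.n_classes)
        self.model_ = plsda_fit(
            X, Y, self.n_components, tol=self.tol, max_iter=self.max_iter
        )
        return self

    def predict(self, X, groups=None):
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        labels, _, n_np = plsda_predict(self.model_, X)
        self.no_positive_count_ += n_np
        return labels
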