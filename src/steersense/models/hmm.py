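"""Hidden Markov model with Gaussian-mixture emissions, trained by Baum-Welch.

The model is fitted unsupervised on the per-steer block-feature sequences:
labels play no role in EM itself. Afterwards, hidden states are matched to
behaviour classes by maximum overlap between the decoded path and the
training labels (Hungarian assignment when the counts permit a bijection).
Decoding uses the most-probable path (Viterbi); posterior-marginal decoding
is available behind a flag.

Numerical choices: all recursions run in log space; covariance updates are
jitter-regularised (``reg`` on the diagonal); EM stops when the absolute
change in total log-likelihood across all sequences drops below ``tol``
(default 0.04) or after ``max_iter`` iterations. Because EM is prone to
local minima, ``n_init`` seeded k-means-style restarts are run and the
highest-likelihood fit kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianMixture:
    """Mixture emission density for one hidden state."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)

    def component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        """log N(x | mu_k, Sigma_k) for each sample and component -> (n, K)."""
        X = np.atleast_2d(X)
        n, d = X.shape
        K = len(self.weights)
        out = np.empty((n, K))
        for k in range(K):
            chol = np.linalg.cholesky(self.covariances[k])
            diff = X - self.means[k]
            sol = solve_triangular(chol, diff.T, lower=True)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (d * _LOG_2PI + logdet + maha)
        return out

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        lp = self.component_log_pdf(X) + np.log(self.weights)
        return logsumexp(lp, axis=1)


@dataclass
class HMMParams:
    """Fitted HMM: start/transition probabilities plus per-state emissions."""

    startprob: np.ndarray
    transmat: np.ndarray
    emissions: list[GaussianMixture]
    state_to_class: np.ndarray  # hidden state index -> class index
    log_likelihoods: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.startprob)


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 25):
    """Plain Lloyd k-means with k-means++ seeding (initialisation helper)."""
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=p)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    assign = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        dist = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(dist, axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for j in range(k):
            mask = assign == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
    return centers, assign


def _init_params(
    X: np.ndarray, n_states: int, mixtures: int, rng: np.random.Generator, reg: float
) -> HMMParams:
    d = X.shape[1]
    centers, assign = _kmeans(X, n_states, rng)
    pooled = np.cov(X.T).reshape(d, d) + reg * np.eye(d)
    emissions = []
    for s in range(n_states):
        Xs = X[assign == s]
        if len(Xs) < 2 * mixtures:
            Xs = X
        if mixtures == 1:
            means = centers[s : s + 1].copy()
            covs = pooled[None, :, :].copy()
            weights = np.ones(1)
        else:
            sub_centers, sub_assign = _kmeans(Xs, mixtures, rng)
            means = sub_centers
            covs = np.stack([pooled.copy() for _ in range(mixtures)])
            weights = np.bincount(sub_assign, minlength=mixtures).astype(float)
            weights = np.maximum(weights, 1.0)
            weights /= weights.sum()
        emissions.append(GaussianMixture(weights=weights, means=means, covariances=covs))
    # mild self-transition bias breaks symmetry towards persistent behaviours
    transmat = np.full((n_states, n_states), 0.2 / max(n_states - 1, 1))
    np.fill_diagonal(transmat, 0.8)
    transmat /= transmat.sum(axis=1, keepdims=True)
    startprob = np.full(n_states, 1.0 / n_states)
    return HMMParams(
        startprob=startprob,
        transmat=transmat,
        emissions=emissions,
        state_to_class=np.arange(n_states),
    )


def _forward_backward(params: HMMParams, logB: np.ndarray):
    """Log-space forward-backward for one sequence.

    Returns (log_gamma, xi_sum, loglik) with ``xi_sum`` the expected
    transition counts summed over time.
    """
    T, S = logB.shape
    log_start = np.log(params.startprob + 1e-300)
    log_A = np.log(params.transmat + 1e-300)
    alpha = np.empty((T, S))
    alpha[0] = log_start + logB[0]
    for t in range(1, T):
        alpha[t] = logB[t] + logsumexp(alpha[t - 1][:, None] + log_A, axis=0)
    ll = float(logsumexp(alpha[-1]))
    beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_A + (logB[t + 1] + beta[t + 1])[None, :], axis=1)
    log_gamma = alpha + beta - ll
    xi_sum = np.zeros((S, S))
    for t in range(1, T):
        log_xi = (
            alpha[t - 1][:, None] + log_A + (logB[t] + beta[t])[None, :] - ll
        )
        xi_sum += np.exp(log_xi)
    return log_gamma, xi_sum, ll


def hmm_fit(
    sequences: list[np.ndarray],
    n_states: int = 3,
    mixtures_per_state: int = 1,
    tol: float = 0.04,
    max_iter: int = 200,
    n_init: int = 3,
    seed: int = 0,
    reg: float = 1e-6,
    label_sequences: list[np.ndarray] | None = None,
    n_classes: int = 3,
) -> HMMParams:
    """Fit by EM over multiple sequences (no transitions across sequence ends)."""
    sequences = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    if not sequences or any(len(s) == 0 for s in sequences):
        raise ValueError("sequences must be non-empty")
    X = np.vstack(sequences)
    if np.ptp(X, axis=0).max() == 0.0:
        raise ValueError("all observations identical; emission fit is degenerate")

    best: HMMParams | None = None
    best_ll = -np.inf
    ss = np.random.SeedSequence(entropy=(int(seed), 17))
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        params = _init_params(X, n_states, mixtures_per_state, rng, reg)
        ll_hist: list[float] = []
        for _ in range(max_iter):
            params, ll = _em_step(params, sequences, reg)
            ll_hist.append(ll)
            if len(ll_hist) > 1 and abs(ll_hist[-1] - ll_hist[-2]) < tol:
                break
        params.log_likelihoods = ll_hist
        if ll_hist[-1] > best_ll:
            best_ll = ll_hist[-1]
            best = params
    assert best is not None

    if label_sequences is not None:
        best.state_to_class = _match_states(best, sequences, label_sequences, n_classes)
    return best


def _em_step(params: HMMParams, sequences: list[np.ndarray], reg: float):
    S = params.n_states
    d = sequences[0].shape[1]
    K = len(params.emissions[0].weights)

    start_acc = np.zeros(S)
    xi_acc = np.zeros((S, S))
    # per state/component sufficient statistics
    r_sum = np.zeros((S, K))
    r_x = np.zeros((S, K, d))
    r_xx = np.zeros((S, K, d, d))
    total_ll = 0.0

    for seq in sequences:
        comp_lp = np.stack(
            [params.emissions[s].component_log_pdf(seq) for s in range(S)], axis=1
        )  # (T, S, K)
        comp_lp = comp_lp + np.log(
            np.stack([params.emissions[s].weights for s in range(S)])
        )
        logB = logsumexp(comp_lp, axis=2)  # (T, S)
        log_gamma, xi_sum, ll = _forward_backward(params, logB)
        total_ll += ll
        gamma = np.exp(log_gamma)
        start_acc += gamma[0]
        xi_acc += xi_sum
        # component responsibilities within each state
        log_resp = comp_lp - logB[:, :, None]
        resp = gamma[:, :, None] * np.exp(log_resp)  # (T, S, K)
        r_sum += resp.sum(axis=0)
        r_x += np.einsum("tsk,td->skd", resp, seq)
        r_xx += np.einsum("tsk,td,te->skde", resp, seq, seq)

    new_start = start_acc / start_acc.sum()
    new_trans = xi_acc / np.maximum(xi_acc.sum(axis=1, keepdims=True), 1e-300)
    emissions = []
    for s in range(S):
        w = r_sum[s] / max(r_sum[s].sum(), 1e-300)
        means = r_x[s] / np.maximum(r_sum[s][:, None], 1e-300)
        covs = np.empty((K, d, d))
        for k in range(K):
            denom = max(r_sum[s, k], 1e-300)
            covs[k] = (
                r_xx[s, k] / denom
                - np.outer(means[k], means[k])
                + reg * np.eye(d)
            )
            covs[k] = 0.5 * (covs[k] + covs[k].T)
            try:
                np.linalg.cholesky(covs[k])
            except np.linalg.LinAlgError:
                logger.warning("singular emission covariance; adding jitter")
                covs[k] += 1e-3 * np.trace(covs[k]) / d * np.eye(d)
        emissions.append(GaussianMixture(weights=w, means=means, covariances=covs))
    return (
        HMMParams(
            startprob=new_start,
            transmat=new_trans,
            emissions=emissions,
            state_to_class=params.state_to_class,
        ),
        total_ll,
    )


def viterbi(params: HMMParams, sequence: np.ndarray) -> np.ndarray:
    """Most-probable hidden path for one sequence."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    S = params.n_states
    logB = np.stack([params.emissions[s].log_pdf(seq) for s in range(S)], axis=1)
    T = len(seq)
    log_A = np.log(params.transmat + 1e-300)
    delta = np.log(params.startprob + 1e-300) + logB[0]
    psi = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def posterior_decode(params: HMMParams, sequence: np.ndarray) -> np.ndarray:
    """Posterior-marginal (per-block argmax) decoding; optional alternative."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    S = params.n_states
    logB = np.stack([params.emissions[s].log_pdf(seq) for s in range(S)], axis=1)
    log_gamma, _, _ = _forward_backward(params, logB)
    return np.argmax(log_gamma, axis=1)


def _match_states(
    params: HMMParams,
    sequences: list[np.ndarray],
    label_sequences: list[np.ndarray],
    n_classes: int,
) -> np.ndarray:
    overlap = np.zeros((params.n_states, n_classes))
    for seq, labs in zip(sequences, label_sequences):
        path = viterbi(params, seq)
        for s, c in zip(path, np.asarray(labs, dtype=int)):
            overlap[s, c] += 1
    if params.n_states == n_classes:
        rows, cols = linear_sum_assignment(-overlap)
        mapping = np.empty(params.n_states, dtype=int)
        mapping[rows] = cols
    else:
        mapping = np.argmax(overlap, axis=1)
    return mapping


def hmm_predict(
    params: HMMParams, sequence: np.ndarray, method: str = "viterbi"
) -> np.ndarray:
    """Class labels (canonical indices) for one time-ordered sequence."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    if seq.shape[1] != params.emissions[0].means.shape[1]:
        raise ValueError("feature dimensionality does not match the fitted model")
    decoder = viterbi if method == "viterbi" else posterior_decode
    return params.state_to_class[decoder(params, seq)]


class HMMClassifier:
    """Sequence-aware classifier facade with the shared fit/predict interface.

    ``groups`` delimits per-steer sequences: rows sharing a group value form
    one time-ordered sequence and no transition is modelled across groups.
    """

    def __init__(
        self,
        n_states: int = 3,
        mixtures_per_state: int = 1,
        tol: float = 0.04,
        max_iter: int = 200,
        n_init: int = 3,
        seed: int = 0,
        decoder: str = "viterbi",
    ):
        self.n_states = n_states
        self.mixtures_per_state = mixtures_per_state
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.seed = seed
        self.decoder = decoder
        self.params_: HMMParams | None = None

    @staticmethod
    def _split(X, y, groups):
        if groups is None:
            return [np.atleast_2d(X)], None if y is None else [np.asarray(y)]
        groups = np.asarray(groups)
        order = []
        seen = set()
        for g in groups:
            if g not in seen:
                seen.add(g)
                order.append(g)
        seqs = [np.atleast_2d(X[groups == g]) for g in order]
        labs = None if y is None else [np.asarray(y)[groups == g] for g in order]
        return seqs, labs

    def fit(self, X, y, groups=None):
        seqs, labs = self._split(np.asarray(X, dtype=float), y, groups)
        self.params_ = hmm_fit(
            seqs,
            n_states=self.n_states,
            mixtures_per_state=self.mixtures_per_state,
            tol=self.tol,
            max_iter=self.max_iter,
            n_init=self.n_init,
            seed=self.seed,
            label_sequences=labs,
        )
        return self

    def predict(self, X, groups=None):
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        seqs, _ = self._split(np.asarray(X, dtype=float), None, groups)
        return np.concatenate(
            [hmm_predict(self.params_, s, method=self.decoder) for s in seqs]
        )
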