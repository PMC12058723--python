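"""Gaussian and time-delay-embedded HMM state inference.

Both paths share the same recipe: z-score parcel courses, optionally
stack lagged copies (time-delay embedding, lags -1..1 by default), reduce
with PCA keeping 60% of variance, fit a zero-mean full-covariance
Gaussian HMM by EM with random restarts, and Viterbi-decode the state
path.  Zero-mean emissions make the states pure covariance patterns: the
Gaussian HMM sees instantaneous covariance only, while the embedded
model's covariance spans lags and is therefore sensitive to spectral and
phase structure.

EM replaces the stochastic variational inference used by some toolboxes:
it is deterministic given the seed and carries the classic monotone
log-likelihood guarantee, and the benchmark treats the inference engine
as a black box scored purely by state recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from scipy import linalg as sla

from .forward_inverse import ParcelData

__all__ = [
    "TDEConfig",
    "HMMModel",
    "StateTimeCourse",
    "time_delay_embed",
    "pca_reduce",
    "fit_hmm",
    "viterbi_decode",
    "run_gaussian_hmm",
    "run_tde_hmm",
]


@dataclass(frozen=True)
class TDEConfig:
    """Embedding lags and PCA variance fraction (defaults: -1..1, 60%)."""

    lags: tuple[int, ...] = (-1, 0, 1)
    pca_variance: float = 0.60
    n_states: int = 10
    n_restarts: int = 5
    max_iter: int = 500
    rel_tol: float = 1e-6
    # seed the first EM restart from the phase-informed segmentation
    # (see segmentation module); the glassy likelihood surface is not
    # reliably navigable from random covariance initializations alone
    phase_informed_init: bool = True

    def __post_init__(self) -> None:
        if list(self.lags) != sorted(set(self.lags)) or 0 not in self.lags:
            raise ValueError("lags must be strictly increasing and contain 0")
        if not (0 < self.pca_variance <= 1):
            raise ValueError("pca_variance must be in (0, 1]")


class _ZeroMeanGaussianHMM(GaussianHMM):
    """Gaussian HMM with emissions fixed at zero mean.

    Excluding 'm' from `params` keeps the means at zero, but hmmlearn
    then also skips accumulating the posterior-mass statistics that the
    covariance M-step divides by; force them on so covariances are the
    posterior-weighted second moments about zero.
    """

    def _needs_sufficient_statistics_for_mean(self) -> bool:
        return True


class _RelativeTolMonitor(ConvergenceMonitor):
    """EM convergence on *relative* log-likelihood improvement.

    Also retains the full per-iteration history (the base class only
    documents the last two entries)."""

    @property
    def converged(self) -> bool:
        if self.iter >= self.n_iter:
            return True
        if len(self.history) < 2:
            return False
        prev, cur = self.history[-2], self.history[-1]
        denom = max(abs(cur), 1.0)
        return (cur - prev) / denom < self.tol


@dataclass
class HMMModel:
    """Fitted zero-mean Gaussian HMM plus its EM trace."""

    n_states: int
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    state_covariances: np.ndarray  # (K, D, D)
    fit_log: list[float] = field(default_factory=list)
    seed: int | None = None
    restart_logs: list[list[float]] = field(default_factory=list)

    def log_emission(self, Y: np.ndarray) -> np.ndarray:
        """(K, T) log N(y_t | 0, Sigma_k)."""
        D, T = Y.shape
        out = np.empty((self.n_states, T))
        for k in range(self.n_states):
            chol = sla.cholesky(self.state_covariances[k], lower=True)
            sol = sla.solve_triangular(chol, Y, lower=True)
            logdet = 2 * np.sum(np.log(np.diag(chol)))
            out[k] = -0.5 * (np.sum(sol**2, axis=0) + logdet + D * np.log(2 * np.pi))
        return out


@dataclass
class StateTimeCourse:
    """Viterbi path plus forward-backward posteriors.

    `offset` maps path index 0 back to its original sample index (the
    left lag span consumed by the embedding).
    """

    path: np.ndarray        # (T',)
    posteriors: np.ndarray  # (K, T')
    offset: int = 0


def time_delay_embed(X: np.ndarray, lags: tuple[int, ...]) -> np.ndarray:
    """Stack lagged copies of X, valid samples only.

    Row ordering is source-major, lag-minor: rows [p*L ... p*L + L - 1]
    hold source p at each lag in order.  Output has P*L rows and
    T - (max(lags) - min(lags)) columns; column c corresponds to original
    sample c - min(lags).
    """
    X = np.asarray(X, dtype=float)
    P, T = X.shape
    lags = tuple(lags)
    span = max(lags) - min(lags)
    if T <= span:
        raise ValueError("series shorter than the lag span")
    Tv = T - span
    L = len(lags)
    out = np.empty((P * L, Tv))
    for p in range(P):
        for li, lag in enumerate(lags):
            start = lag - min(lags)
            out[p * L + li] = X[p, start:start + Tv]
    return out


def pca_reduce(X: np.ndarray, variance_fraction: float) -> tuple[np.ndarray, dict]:
    """Project onto the smallest set of PCs reaching the variance fraction.

    Returns (scores [D x T], info) where info holds the mean, components
    and explained-variance spectrum needed for reconstruction.  PC signs
    are fixed so each component's largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    total = np.sum(Xc**2)
    if total == 0:
        raise ValueError("zero-variance input")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    if variance_fraction >= 1.0:
        D = int(np.sum(var > var[0] * 1e-12))  # numerical rank
    else:
        D = int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
    # deterministic sign: largest-|loading| entry of each component positive
    for d in range(D):
        j = np.argmax(np.abs(U[:, d]))
        if U[j, d] < 0:
            U[:, d] = -U[:, d]
            Vt[d] = -Vt[d]
    scores = U[:, :D].T @ Xc
    info = dict(mean=mean, components=U[:, :D], explained_variance=var[:D] / var.sum(),
                singular_values=s[:D])
    return scores, info


def _labels_to_covariances(Y: np.ndarray, labels: np.ndarray,
                           n_states: int) -> np.ndarray:
    """Zero-mean covariance per state from a hard label sequence."""
    D, T = Y.shape
    covs = np.empty((n_states, D, D))
    reg = 1e-6 * np.eye(D)
    for k in range(n_states):
        idx = labels == k
        if idx.sum() <= D:
            covs[k] = (Y @ Y.T) / T + reg
        else:
            seg = Y[:, idx]
            covs[k] = (seg @ seg.T) / idx.sum() + reg
    return covs


def _init_model(Y: np.ndarray, n_states: int, cfg: TDEConfig,
                rng: np.random.Generator,
                init_labels: np.ndarray | None = None) -> GaussianHMM:
    D, T = Y.shape
    model = _ZeroMeanGaussianHMM(n_components=n_states, covariance_type="full",
                                 params="stc", init_params="", n_iter=cfg.max_iter,
                                 tol=cfg.rel_tol, min_covar=1e-6)
    # weak inverse-Wishart-style prior keeps the covariance update positive
    # definite even when a state's posterior mass collapses to zero
    model.covars_prior = np.tile(1e-2 * np.eye(D), (n_states, 1, 1))
    model.covars_weight = D + 2
    model.startprob_ = rng.dirichlet(np.ones(n_states))
    if init_labels is not None:
        # sticky start at the dwell scale; covariances from the segmentation
        p_stay = 1 - 1 / 64
        model.transmat_ = np.full((n_states, n_states),
                                  (1 - p_stay) / max(n_states - 1, 1))
        np.fill_diagonal(model.transmat_, p_stay)
        model.means_ = np.zeros((n_states, D))
        model.covars_ = _labels_to_covariances(Y, init_labels, n_states)
        return model
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    model.transmat_ = 0.8 * np.eye(n_states) + 0.2 * trans  # sticky start
    model.means_ = np.zeros((n_states, D))
    # data-informed distinct covariances: one random contiguous window per state
    win = min(max(D + 1, 64), T)
    covs = np.empty((n_states, D, D))
    reg = 1e-6 * np.eye(D)
    for k in range(n_states):
        start = int(rng.integers(0, max(T - win, 1)))
        seg = Y[:, start:start + win]
        covs[k] = np.cov(seg) + np.var(seg) * 1e-3 * np.eye(D) + reg
    model.covars_ = covs
    return model


def fit_hmm(Y: np.ndarray, n_states: int, n_restarts: int = 5,
            seed: int | None = None, cfg: TDEConfig | None = None,
            init_labels: np.ndarray | None = None) -> HMMModel:
    """Baum-Welch EM with zero-mean full-covariance Gaussian emissions.

    `Y` is (features x time), expected z-scored (session-concatenated)
    input.  Runs `n_restarts` independent EM fits (per-restart seeds
    derived from `seed`) and returns the best by final log-likelihood.
    When `init_labels` (a hard state sequence over Y's columns, e.g.
    from a phase-informed segmentation) is given, the first restart
    starts from that segmentation's covariances; remaining restarts use
    random data-informed initializations.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (features x time)")
    cfg = cfg or TDEConfig(n_states=n_states, n_restarts=n_restarts)
    D, T = Y.shape
    if T < n_states:
        raise ValueError("fewer samples than states")
    if n_states == 1:
        cov = np.atleast_2d(np.cov(Y)) + 1e-6 * np.eye(D)
        return HMMModel(n_states=1, transition_matrix=np.ones((1, 1)),
                        initial_probs=np.ones(1), state_covariances=cov[None],
                        fit_log=[], seed=seed)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(n_restarts)
    best = None
    best_ll = -np.inf
    restart_logs: list[list[float]] = []
    for r in range(n_restarts):
        rng = np.random.default_rng(children[r])
        labels = init_labels if r == 0 else None
        model = _init_model(Y, n_states, cfg, rng, init_labels=labels)
        model.monitor_ = _RelativeTolMonitor(model.tol, model.n_iter, False)
        model.fit(Y.T)
        history = list(model.monitor_.history)
        restart_logs.append(history)
        ll = history[-1] if history else -np.inf
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite likelihood in restart {r}")
        if ll > best_ll:
            best_ll = ll
            best = model
    assert best is not None
    covs = np.array(best.covars_)
    return HMMModel(n_states=n_states, transition_matrix=np.array(best.transmat_),
                    initial_probs=np.array(best.startprob_),
                    state_covariances=covs,
                    fit_log=restart_logs[int(np.argmax([lg[-1] for lg in restart_logs]))],
                    seed=seed, restart_logs=restart_logs)


def viterbi_decode(model: HMMModel, Y: np.ndarray, offset: int = 0) -> StateTimeCourse:
    """Log-domain Viterbi MAP path; ties break toward the lower state index.

    Posteriors come from the standard scaled forward-backward pass.
    """
    Y = np.asarray(Y, dtype=float)
    K = model.n_states
    if Y.shape[0] != model.state_covariances.shape[1]:
        raise ValueError("observation dimension does not match the model")
    logB = model.log_emission(Y)  # (K, T)
    T = logB.shape[1]
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition_matrix)
        logpi = np.log(model.initial_probs)
    delta = logpi + logB[:, 0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[back[t], np.arange(K)] + logB[:, t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    post = _forward_backward(logpi, logA, logB)
    return StateTimeCourse(path=path, posteriors=post, offset=offset)


def _forward_backward(logpi: np.ndarray, logA: np.ndarray,
                      logB: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    K, T = logB.shape
    la = np.empty((T, K))
    lb = np.zeros((T, K))
    la[0] = logpi + logB[:, 0]
    for t in range(1, T):
        la[t] = logB[:, t] + logsumexp(la[t - 1][:, None] + logA, axis=0)
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA + (logB[:, t + 1] + lb[t + 1])[None, :], axis=1)
    lg = la + lb
    lg -= logsumexp(lg, axis=1, keepdims=True)
    return np.exp(lg).T


def _zscore(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant row cannot be z-scored")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def _segmentation_labels(Z: np.ndarray, cfg: TDEConfig) -> np.ndarray | None:
    if not cfg.phase_informed_init:
        return None
    from .segmentation import phase_segmentation

    return phase_segmentation(Z, cfg.n_states)


def run_gaussian_hmm(parcels: ParcelData, cfg: TDEConfig,
                     seed: int | None = None) -> tuple[StateTimeCourse, HMMModel]:
    """z-score -> PCA(variance fraction) -> zero-mean HMM -> Viterbi."""
    Z = _zscore(parcels.data)
    Y, _ = pca_reduce(Z, cfg.pca_variance)
    labels = _segmentation_labels(Z, cfg)
    model = fit_hmm(Y, cfg.n_states, cfg.n_restarts, seed=seed, cfg=cfg,
                    init_labels=labels)
    return viterbi_decode(model, Y, offset=0), model


def run_tde_hmm(parcels: ParcelData, cfg: TDEConfig,
                seed: int | None = None) -> tuple[StateTimeCourse, HMMModel]:
    """z-score -> time-delay embed -> PCA -> zero-mean HMM -> Viterbi.

    The decoded path is re-aligned to original sample indices via the
    returned `offset` (= -min(lags))."""
    Z = _zscore(parcels.data)
    E = time_delay_embed(Z, cfg.lags)
    Y, _ = pca_reduce(E, cfg.pca_variance)
    labels = _segmentation_labels(Z, cfg)
    if labels is not None:
        off = -min(cfg.lags)
        labels = labels[off:off + Y.shape[1]]
    model = fit_hmm(Y, cfg.n_states, cfg.n_restarts, seed=seed, cfg=cfg,
                    init_labels=labels)
    return viterbi_decode(model, Y, offset=-min(cfg.lags)), model
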