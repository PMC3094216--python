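"""Gaussian-mixture-emission hidden Markov model.

The generative model: a hidden state sequence ``S_t`` over ``Q`` states
follows a first-order Markov chain with time-invariant transition matrix
``a_ij`` and initial distribution ``pi``.  Each state ``j`` emits a
D-dimensional observation from a mixture of ``M`` Gaussians,

    b_j(x) = sum_k w_jk N(x; mu_jk, Sigma_jk),   sum_k w_jk = 1.

Inference uses the scaled forward-backward recursions (per-step
normalization constants accumulate the log-likelihood, so sequences of up
to ~1e5 windows are handled without underflow).  Training is Baum-Welch EM
with k-means++ initialization of the cluster means, covariance flooring,
multi-restart selection by final log-likelihood, and support for multiple
observation sequences (per-sequence sufficient statistics are summed before
the M-step).  Decoding is by the marginal state posterior ``gamma_i(t)``,
not Viterbi.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans, kmeans_plusplus

from .features import FeatureMatrix

__all__ = [
    "FeatureScaler",
    "GmmHmmModel",
    "PosteriorSet",
    "FitResult",
    "gaussian_pdf",
    "emission_prob",
    "forward_backward",
    "em_fit",
    "decode",
]

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class FeatureScaler:
    """Per-dimension location/scale (z-scoring) frozen at training time."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("scaler std must be positive")

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        std = x.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)
        return cls(x.mean(axis=0), std)


@dataclass
class GmmHmmModel:
    """Q-state, M-cluster Gaussian-mixture HMM.

    Attributes
    ----------
    a : (Q, Q) transition matrix, rows sum to 1.
    pi : (Q,) initial state distribution.
    w : (Q, M) mixture weights, rows sum to 1.
    mu : (Q, M, D) component means.
    sigma : (Q, M, D, D) symmetric positive-definite covariances.
    feature_scaler : optional z-scoring applied to observations before
        evaluating emission densities (stored from training).
    """

    a: np.ndarray
    pi: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    feature_scaler: Optional[FeatureScaler] = None
    band_labels: Optional[list[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.ndim == 2:  # (Q, D) shorthand for M = 1
            self.mu = self.mu[:, None, :]
        if self.sigma.ndim == 3:
            self.sigma = self.sigma[:, None, :, :]

    @property
    def Q(self) -> int:
        return self.a.shape[0]

    @property
    def M(self) -> int:
        return self.w.shape[1]

    @property
    def D(self) -> int:
        return self.mu.shape[2]

    @property
    def n_parameters(self) -> int:
        """Parameter count K = 3QM + Q^2 used by the AICc penalty."""
        return 3 * self.Q * self.M + self.Q * self.Q

    def validate(self, atol: float = 1e-8) -> None:
        Q, M, D = self.Q, self.M, self.D
        if self.a.shape != (Q, Q) or self.pi.shape != (Q,):
            raise ValueError("transition/initial distribution shape mismatch")
        if self.w.shape != (Q, M) or self.mu.shape != (Q, M, D):
            raise ValueError("mixture parameter shape mismatch")
        if self.sigma.shape != (Q, M, D, D):
            raise ValueError("covariance shape mismatch")
        if np.any(self.a < -atol) or np.any(self.pi < -atol) or np.any(self.w < -atol):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.a.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        if not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.w.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1 per state")
        for j in range(Q):
            for k in range(M):
                s = self.sigma[j, k]
                if not np.allclose(s, s.T, atol=1e-8):
                    raise ValueError("covariances must be symmetric")
                try:
                    np.linalg.cholesky(s)
                except np.linalg.LinAlgError as exc:
                    raise ValueError("covariances must be positive definite") from exc

    # ---- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "Q": self.Q, "M": self.M, "D": self.D,
            "a": self.a.tolist(), "pi": self.pi.tolist(), "w": self.w.tolist(),
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "feature_scaler": None, "band_labels": self.band_labels,
            "meta": self.meta,
        }
        if self.feature_scaler is not None:
            d["feature_scaler"] = {
                "mean": self.feature_scaler.mean.tolist(),
                "std": self.feature_scaler.std.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GmmHmmModel":
        scaler = None
        if d.get("feature_scaler") is not None:
            scaler = FeatureScaler(np.array(d["feature_scaler"]["mean"]),
                                   np.array(d["feature_scaler"]["std"]))
        return cls(
            a=np.array(d["a"]), pi=np.array(d["pi"]), w=np.array(d["w"]),
            mu=np.array(d["mu"]), sigma=np.array(d["sigma"]),
            feature_scaler=scaler, band_labels=d.get("band_labels"),
            meta=d.get("meta", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GmmHmmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PosteriorSet:
    """Forward-backward quantities for one observation sequence.

    ``gamma[t, i]`` is the marginal posterior P(S_t = i | x_{1:T});
    ``zeta[t, i, j]`` is P(S_t = i, S_{t+1} = j | x_{1:T});
    ``resp[t, j, k]`` the per-cluster responsibility, summing over k to
    ``gamma[t, j]``; ``loglik`` the total sequence log-likelihood.
    """

    log_alpha: np.ndarray
    log_beta: np.ndarray
    gamma: np.ndarray
    zeta: np.ndarray
    resp: np.ndarray
    loglik: float


@dataclass
class FitResult:
    model: GmmHmmModel
    ll_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# densities


def _log_gaussian(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log multivariate normal density of rows of ``x`` (T, D)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    D = x.shape[1]
    chol = np.linalg.cholesky(sigma)  # raises LinAlgError if not SPD
    dev = solve_triangular(chol, (x - mu).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (D * _LOG2PI + logdet + np.sum(dev * dev, axis=0))


def gaussian_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Multivariate normal density N(x; mu, sigma); sigma must be SPD."""
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    try:
        val = _log_gaussian(x[None, :], mu, sigma)[0]
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be symmetric positive definite") from exc
    return float(np.exp(val))


def _log_emission_components(x: np.ndarray, model: GmmHmmModel) -> np.ndarray:
    """(T, Q, M) array of log(w_jk) + log N(x_t; mu_jk, Sigma_jk)."""
    T = x.shape[0]
    out = np.full((T, model.Q, model.M), -np.inf)
    with np.errstate(divide="ignore"):
        logw = np.log(model.w)
    for j in range(model.Q):
        for k in range(model.M):
            if model.w[j, k] <= 0:
                continue
            out[:, j, k] = logw[j, k] + _log_gaussian(x, model.mu[j, k], model.sigma[j, k])
    return out


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis=axis)
    return out


def emission_prob(x: np.ndarray, model: GmmHmmModel, j: int) -> float:
    """Mixture emission density b_j(x) for state ``j`` (0-based)."""
    xs = np.asarray(x, dtype=float).ravel()[None, :]
    if model.feature_scaler is not None:
        xs = model.feature_scaler.transform(xs)
    comp = _log_emission_components(xs, model)[0, j]
    return float(np.exp(_logsumexp(comp[None, :], axis=1)[0]))


# ---------------------------------------------------------------------------
# inference


def _as_array(f: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    return f.x if isinstance(f, FeatureMatrix) else np.atleast_2d(np.asarray(f, float))


def forward_backward(model: GmmHmmModel, f: Union[FeatureMatrix, np.ndarray]) -> PosteriorSet:
    """Scaled forward-backward inference; returns posteriors and log-likelihood.

    Works in a per-step-normalized domain, so gamma rows, zeta slices and
    cluster responsibilities are exactly normalized and T can be large
    without underflow.
    """
    x = _as_array(f)
    if x.shape[1] != model.D:
        raise ValueError(f"feature dimension {x.shape[1]} != model D {model.D}")
    if model.feature_scaler is not None:
        x = model.feature_scaler.transform(x)

    T, Q = x.shape[0], model.Q
    log_comp = _log_emission_components(x, model)      # (T, Q, M)
    log_b = _logsumexp(log_comp, axis=2)               # (T, Q)
    m = log_b.max(axis=1)                              # per-step emission scale
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite emission log-density")
    B = np.exp(log_b - m[:, None])

    A = model.a
    alpha_hat = np.empty((T, Q))
    c = np.empty(T)
    v = model.pi * B[0]
    c[0] = v.sum()
    alpha_hat[0] = v / c[0]
    for t in range(1, T):
        v = (alpha_hat[t - 1] @ A) * B[t]
        c[t] = v.sum()
        alpha_hat[t] = v / c[t]
    loglik = float(np.sum(np.log(c) + m))

    beta_hat = np.empty((T, Q))
    beta_hat[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta_hat[t] = (A @ (B[t + 1] * beta_hat[t + 1])) / c[t + 1]

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)

    if T > 1:
        zeta = alpha_hat[:-1, :, None] * A[None, :, :] * \
            (B[1:] * beta_hat[1:])[:, None, :] / c[1:, None, None]
    else:
        zeta = np.zeros((0, Q, Q))

    # cluster responsibilities: resp[t,j,k] = gamma[t,j] * w_jk N_jk / b_j
    with np.errstate(invalid="ignore"):
        frac = np.exp(log_comp - log_b[:, :, None])
    frac = np.nan_to_num(frac, nan=0.0)
    resp = gamma[:, :, None] * frac

    # log-domain alpha/beta for inspection: recover from scaled quantities
    logC = np.log(c) + m
    log_alpha = np.log(np.maximum(alpha_hat, 1e-300)) + np.cumsum(logC)[:, None]
    tail = np.concatenate([np.cumsum(logC[::-1])[::-1][1:], [0.0]])
    log_beta = np.log(np.maximum(beta_hat, 1e-300)) + tail[:, None]

    return PosteriorSet(log_alpha, log_beta, gamma, zeta, resp, loglik)


def decode(model: GmmHmmModel, f: Union[FeatureMatrix, np.ndarray]) -> tuple[np.ndarray, PosteriorSet]:
    """Posterior decoding: argmax_i gamma_i(t) per window (ties -> lowest index)."""
    post = forward_backward(model, f)
    return post.gamma.argmax(axis=1), post


# ---------------------------------------------------------------------------
# training


def _floor_covariance(sigma: np.ndarray, floor_diag: np.ndarray) -> np.ndarray:
    """Symmetrize and add a diagonal floor; escalate jitter until SPD."""
    s = 0.5 * (sigma + sigma.T) + np.diag(floor_diag)
    jitter = floor_diag.mean() if floor_diag.mean() > 0 else 1e-10
    for _ in range(12):
        try:
            np.linalg.cholesky(s)
            return s
        except np.linalg.LinAlgError:
            s = s + np.eye(s.shape[0]) * jitter
            jitter *= 10.0
    raise FloatingPointError("covariance could not be regularized to SPD")


def _init_model(xs: list[np.ndarray], Q: int, M: int, rng: np.random.Generator,
                cov_floor: float, diag_cov: bool) -> GmmHmmModel:
    """Hierarchical seeding: states from a Q-means partition of the pooled
    windows, then M k-means++ sub-centers within each state's points.
    Keeping a state's components in the same region of feature space avoids
    the local optima that random center-to-state groupings fall into."""
    X = np.vstack(xs)
    D = X.shape[1]
    gcov = np.cov(X.T, ddof=0).reshape(D, D) if D > 1 else np.array([[X.var()]])
    if diag_cov:
        gcov = np.diag(np.diag(gcov))
    floor = cov_floor * np.maximum(np.diag(gcov), 1e-12)
    gcov = _floor_covariance(gcov, floor)

    mu = np.empty((Q, M, D))
    sigma = np.empty((Q, M, D, D))
    if X.shape[0] >= Q * M and Q > 1:
        km = KMeans(n_clusters=Q, n_init=1,
                    random_state=int(rng.integers(2 ** 31))).fit(X)
        assign = km.labels_
    else:
        assign = rng.integers(0, Q, size=X.shape[0])
    for j in range(Q):
        pts = X[assign == j]
        if pts.shape[0] < max(M, 2):
            pts = X[rng.integers(0, X.shape[0], size=max(M, 2))]
        if M == 1:
            mu[j, 0] = pts.mean(axis=0)
        elif pts.shape[0] >= M:
            centers, _ = kmeans_plusplus(pts, n_clusters=M,
                                         random_state=int(rng.integers(2 ** 31)))
            mu[j] = centers
        else:
            mu[j] = pts[rng.integers(0, pts.shape[0], size=M)]
        scov = np.cov(pts.T, ddof=0).reshape(D, D) if D > 1 else np.array([[pts.var()]])
        if diag_cov:
            scov = np.diag(np.diag(scov))
        sigma[j] = _floor_covariance(scov, floor)
    w = np.full((Q, M), 1.0 / M)
    a = np.full((Q, Q), 1.0 / Q) + rng.uniform(-0.01 / Q, 0.01 / Q, size=(Q, Q))
    a = np.abs(a)
    a /= a.sum(axis=1, keepdims=True)
    pi = np.full(Q, 1.0 / Q)
    return GmmHmmModel(a=a, pi=pi, w=w, mu=mu, sigma=sigma)


def _em_once(xs: list[np.ndarray], Q: int, M: int, rng: np.random.Generator,
             max_iter: int, tol: float, cov_floor: float, diag_cov: bool) -> tuple[GmmHmmModel, list[float]]:
    model = _init_model(xs, Q, M, rng, cov_floor, diag_cov)
    X = np.vstack(xs)
    D = X.shape[1]
    gvar = X.var(axis=0, ddof=0)
    floor = cov_floor * np.maximum(gvar, 1e-12)
    ll_trace: list[float] = []
    for it in range(max_iter):
        # E-step, accumulated over sequences
        ll = 0.0
        zeta_sum = np.zeros((Q, Q))
        gamma_head = np.zeros(Q)          # gamma at t=0, summed over sequences
        gamma_trans = np.zeros(Q)         # sum_t<T-1 gamma (a denominator)
        r_sum = np.zeros((Q, M))
        r_x = np.zeros((Q, M, D))
        r_xx = np.zeros((Q, M, D, D))
        for x in xs:
            post = forward_backward(model, x)
            ll += post.loglik
            zeta_sum += post.zeta.sum(axis=0)
            gamma_head += post.gamma[0]
            gamma_trans += post.gamma[:-1].sum(axis=0)
            r_sum += post.resp.sum(axis=0)
            r_x += np.einsum("tjk,td->jkd", post.resp, x)
            r_xx += np.einsum("tjk,td,te->jkde", post.resp, x, x)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood during EM")
        ll_trace.append(ll)

        # M-step
        pi = gamma_head / gamma_head.sum()
        a_den = np.maximum(gamma_trans, 1e-300)
        a = zeta_sum / a_den[:, None]
        a = np.maximum(a, 0.0)
        rows = a.sum(axis=1, keepdims=True)
        a = np.where(rows > 0, a / np.maximum(rows, 1e-300), 1.0 / Q)

        w = np.empty((Q, M))
        mu = np.empty((Q, M, D))
        sigma = np.empty((Q, M, D, D))
        state_mass = np.maximum(r_sum.sum(axis=1), 1e-300)
        for j in range(Q):
            for k in range(M):
                mass = r_sum[j, k]
                if mass < 1e-8:
                    # empty cluster: re-seed from a random observation
                    log.warning("empty cluster (state %d, component %d); re-seeding", j, k)
                    idx = int(rng.integers(0, X.shape[0]))
                    mu[j, k] = X[idx]
                    base = np.cov(X.T, ddof=0).reshape(D, D) if D > 1 else np.array([[X.var()]])
                    if diag_cov:
                        base = np.diag(np.diag(base))
                    sigma[j, k] = _floor_covariance(base, floor)
                    w[j, k] = 1e-3
                    continue
                mu[j, k] = r_x[j, k] / mass
                cov = r_xx[j, k] / mass - np.outer(mu[j, k], mu[j, k])
                if diag_cov:
                    cov = np.diag(np.diag(cov))
                sigma[j, k] = _floor_covariance(cov, floor)
                w[j, k] = mass / state_mass[j]
        w /= w.sum(axis=1, keepdims=True)

        model = GmmHmmModel(a=a, pi=pi, w=w, mu=mu, sigma=sigma)

        if it > 0:
            prev = ll_trace[-2]
            if (ll - prev) < tol * abs(prev):
                break
    return model, ll_trace


def em_fit(f: Union[FeatureMatrix, np.ndarray, Sequence[Union[FeatureMatrix, np.ndarray]]],
           Q: int, M: int, seed: int = 0, max_iter: int = 200, tol: float = 1e-4,
           n_restarts: int = 5, standardize: bool = True,
           cov_floor: float = 1e-6, diag_cov: bool = False,
           band_labels: Optional[list[str]] = None) -> FitResult:
    """Baum-Welch training of a Q-state, M-cluster model.

    ``f`` may be a single feature matrix/array or a sequence of them
    (multi-sequence EM: sufficient statistics are summed across sequences).
    With ``standardize`` the features are z-scored per dimension and the
    scaler is stored on the returned model, so inference on new data reuses
    the training statistics.  ``n_restarts`` independent initializations are
    run and the fit with the best final log-likelihood kept.

    Convergence: relative log-likelihood improvement below ``tol`` (default
    1e-4) or ``max_iter`` iterations.
    """
    if not (1 <= Q <= 10):
        raise ValueError("Q must be in 1..10")
    if not (1 <= M <= 5):
        raise ValueError("M must be in 1..5")
    if isinstance(f, (FeatureMatrix, np.ndarray)):
        seqs = [f]
    else:
        seqs = list(f)
    if band_labels is None and isinstance(seqs[0], FeatureMatrix):
        band_labels = list(seqs[0].band_labels)
    xs = [_as_array(s) for s in seqs]
    total_T = sum(x.shape[0] for x in xs)
    if total_T < Q * M:
        raise ValueError(f"need at least Q*M={Q * M} windows, got {total_T}")

    scaler = None
    if standardize:
        scaler = FeatureScaler.fit(np.vstack(xs))
        xs = [scaler.transform(x) for x in xs]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(1, n_restarts))
    best: Optional[tuple[GmmHmmModel, list[float]]] = None
    for child in children:
        rng = np.random.default_rng(child)
        try:
            model, trace = _em_once(xs, Q, M, rng, max_iter, tol, cov_floor, diag_cov)
        except FloatingPointError as exc:
            log.warning("EM restart failed (%s); skipping", exc)
            continue
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    if best is None:
        raise FloatingPointError("all EM restarts failed with non-finite likelihood")
    model, trace = best
    model.feature_scaler = scaler
    model.band_labels = band_labels
    model.meta = {"seed": seed, "loglik": trace[-1], "Q": Q, "M": M,
                  "n_restarts": n_restarts, "standardize": standardize}
    converged = len(trace) < max_iter
    return FitResult(model=model, ll_trace=np.asarray(trace), n_iter=len(trace),
                     converged=converged, seed=seed)
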