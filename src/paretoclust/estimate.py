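"""The Pareto-clustering estimator: an MM (minorize-maximization) iteration.

Each sweep updates, in this order, (1) the membership matrix ``q_k(x_i)``
(responsibilities), (2) the centers with ``q^{1+beta}`` weights, (3) the
covariances from the *new* centers with the ``tau * (2 - d*beta)`` scale and a
ridge blend, and (4) the mixing proportions from the new centers and
covariances.  This order is what makes the surrogate a true minorizer, so the
generalized energy decreases monotonically along the iteration.

``tau = math.inf`` selects an analytic branch (floating-point ``tau`` cannot
reach the fuzzy/k-means regime reliably): with ``beta > 0`` the updates are
exactly classic fuzzy c-means with ``m = 1 + beta`` (identity covariances,
uniform proportions), and with ``beta = 0`` they are Lloyd's k-means
iteration.

Initialization follows the mclust tradition: a Ward-linkage agglomeration cut
at K groups supplies initial centers, covariances and proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

from .energy import (
    ClusterParams,
    Hyperparams,
    _as_matrix,
    fuzzy_energy,
    kmeans_energy,
    log_component_weights,
    pareto_energy,
    sq_distances,
)

__all__ = [
    "MembershipMatrix",
    "FitResult",
    "EmptyClusterError",
    "DegenerateScaleError",
    "ConvergenceError",
    "init_params",
    "responsibilities",
    "update_centers",
    "update_covariances",
    "update_proportions",
    "fit",
    "assign",
    "fcm_reference",
    "make_hyperparams",
]

_DENOM_FLOOR = 1e-300


class EmptyClusterError(RuntimeError):
    """A component's effective membership mass vanished."""

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(message or f"component {component} has no effective members")


class DegenerateScaleError(ValueError):
    """The covariance update scale tau*(2 - d*beta) is not positive.

    Raised when covariance estimation is requested with d*beta >= 2; lower
    beta below 2/d or disable covariance estimation (estimate_cov=False).
    """


class ConvergenceError(RuntimeError):
    """The iteration could not recover from repeated empty clusters."""


@dataclass(frozen=True)
class MembershipMatrix:
    """Row-stochastic soft assignments q_k(x_i), shape (n, K)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.values, dtype=float)
        if q.ndim != 2:
            raise ValueError("membership matrix must be 2-d")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("membership values must lie in [0, 1]")
        if np.max(np.abs(q.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("membership rows must sum to 1")
        q = q.copy()
        q.setflags(write=False)
        object.__setattr__(self, "values", q)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit`.

    ``energy_trace[t]`` is the generalized energy after sweep ``t``
    (``energy_trace[0]`` is the energy at the initial parameters), and is
    non-increasing along the iteration.  ``labels`` are 1-based hard
    assignments ``argmax_k q_k(x_i)`` with ties broken toward the lowest
    cluster index.
    """

    params: ClusterParams
    membership: MembershipMatrix
    labels: np.ndarray
    energy_trace: np.ndarray
    n_iter: int
    converged: bool
    n_reseeds: int = 0


def _q_values(Q) -> np.ndarray:
    return np.asarray(getattr(Q, "values", Q), dtype=float)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _ridge_blend(sigma: np.ndarray, alpha: float) -> np.ndarray:
    """alpha * Sigma + (1 - alpha) * sigma2 * I with sigma2 = max diagonal entry."""
    sigma2 = float(np.max(np.diag(sigma)))
    d = sigma.shape[0]
    out = alpha * sigma + (1.0 - alpha) * sigma2 * np.eye(d)
    return 0.5 * (out + out.T)


def init_params(X, K: int, seed: int | None = None, ridge_alpha: float = 0.95,
                trim: float = 0.01) -> ClusterParams:
    """Hierarchical (Ward-linkage) initialization of the mixture parameters.

    The linkage is computed on the points whose distance from the
    coordinate-wise median falls below the ``1 - trim`` quantile: the target
    densities this package fits have polynomial tails, and a handful of
    extreme draws otherwise hijack entire agglomerative branches, seeding a
    component on outliers instead of a mode.  ``trim = 0`` restores the plain
    Ward cut.  Deterministic given (X, K); ``seed`` is accepted for interface
    symmetry but unused.  Singleton or degenerate initial groups receive the
    overall variance times the identity as covariance.
    """
    X = _as_matrix(X)
    n, d = X.shape
    if not 1 <= K <= n:
        raise ValueError(f"K must satisfy 1 <= K <= n, got K={K}, n={n}")
    Xt = X
    if 0 < trim < 1 and K < n:
        r = np.sqrt(((X - np.median(X, axis=0)) ** 2).sum(axis=1))
        keep = r <= np.quantile(r, 1.0 - trim)
        if keep.sum() > K:
            Xt = X[keep]
    if K == len(Xt):
        groups = np.arange(1, len(Xt) + 1)
    else:
        groups = fcluster(linkage(Xt, method="ward"), t=K, criterion="maxclust")
    overall = float(np.var(Xt)) or 1.0
    centers = np.empty((K, d))
    covs = np.empty((K, d, d))
    props = np.empty(K)
    for k in range(K):
        members = Xt[groups == k + 1]
        # degenerate data can leave a requested group empty; park it at the
        # grand mean with zero mass and let the fitter's re-seeding handle it
        centers[k] = members.mean(axis=0) if len(members) else Xt.mean(axis=0)
        props[k] = len(members) / len(Xt)
        if len(members) < 2:
            covs[k] = overall * np.eye(d)
            continue
        raw = np.atleast_2d(np.cov(members, rowvar=False))
        sigma = _ridge_blend(raw, ridge_alpha)
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            sigma = overall * np.eye(d)
        covs[k] = sigma
    return ClusterParams(centers, covs, props)


# ---------------------------------------------------------------------------
# the four update operators
# ---------------------------------------------------------------------------

def _log_responsibilities(X, theta: ClusterParams, tau: float, beta: float) -> np.ndarray:
    logw = log_component_weights(X, theta, tau, beta)
    with np.errstate(divide="ignore"):
        num = logw + np.log(theta.proportions)[None, :]
    norm = logsumexp(num, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        i = int(np.argmax(~np.isfinite(norm.ravel())))
        raise FloatingPointError(f"total membership weight underflowed for point {i}")
    return num - norm


def _log_q_tau_inf(X, centers, beta: float) -> np.ndarray:
    """Analytic tau = inf memberships: q propto (d^2)^{-1/beta} (one-hot at beta=0
    or at exact point-center coincidences, ties toward the lowest index)."""
    d2 = sq_distances(X, centers)
    n, K = d2.shape
    logq = np.full((n, K), -np.inf)
    if beta == 0.0:
        logq[np.arange(n), d2.argmin(axis=1)] = 0.0
        return logq
    hit = d2 == 0.0
    rows_hit = hit.any(axis=1)
    with np.errstate(divide="ignore"):
        raw = -np.log(d2, where=~hit, out=np.full_like(d2, np.inf)) / beta
    reg = ~rows_hit
    logq[reg] = raw[reg] - logsumexp(raw[reg], axis=1, keepdims=True)
    logq[np.nonzero(rows_hit)[0], hit.argmax(axis=1)[rows_hit]] = 0.0
    return logq


def responsibilities(X, theta: ClusterParams, tau: float, beta: float) -> MembershipMatrix:
    """The membership matrix q_k(x_i) = pi_k w_ik / sum_l pi_l w_il."""
    if math.isinf(tau):
        logq = _log_q_tau_inf(X, theta.centers, beta)
    else:
        logq = _log_responsibilities(X, theta, tau, beta)
    return MembershipMatrix(np.exp(logq))


def _powered_weights(Q, beta: float) -> np.ndarray:
    """q^{1+beta} computed through log q, so small memberships keep precision."""
    q = _q_values(Q)
    with np.errstate(divide="ignore"):
        logq = np.log(q, where=q > 0, out=np.full_like(q, -np.inf))
    return np.exp((1.0 + beta) * logq)


def update_centers(X, Q, beta: float) -> np.ndarray:
    """mu_k = sum_i q_k(x_i)^{1+beta} x_i / sum_i q_k(x_i)^{1+beta}."""
    X = _as_matrix(X)
    W = _powered_weights(Q, beta)
    denom = W.sum(axis=0)
    if np.any(denom < _DENOM_FLOOR):
        raise EmptyClusterError(int(np.argmin(denom)))
    return (W.T @ X) / denom[:, None]


def update_covariances(X, Q, centers, tau: float, beta: float,
                       ridge_alpha: float = 0.95) -> np.ndarray:
    """Sigma_k = tau*(2 - d*beta) * weighted scatter about the new centers,
    ridge-blended with its largest diagonal entry times the identity."""
    X = _as_matrix(X)
    centers = _as_matrix(centers)
    d = X.shape[1]
    coef = tau * (2.0 - d * beta)
    if coef <= 0:
        raise DegenerateScaleError(
            f"covariance update scale tau*(2 - d*beta) = {coef:.3g} <= 0 for d={d}, "
            f"beta={beta}; lower beta below {2.0 / d:.3g} or set estimate_cov=False"
        )
    W = _powered_weights(Q, beta)
    denom = W.sum(axis=0)
    if np.any(denom < _DENOM_FLOOR):
        raise EmptyClusterError(int(np.argmin(denom)))
    K = centers.shape[0]
    covs = np.empty((K, d, d))
    for k in range(K):
        diff = X - centers[k]
        raw = coef * (W[:, k, None] * diff).T @ diff / denom[k]
        sigma = _ridge_blend(raw, ridge_alpha)
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            raise EmptyClusterError(k, f"component {k} collapsed to a degenerate scatter")
        covs[k] = sigma
    return covs


def update_proportions(X, Q, theta_new: ClusterParams, tau: float, beta: float) -> np.ndarray:
    """pi_k propto { sum_i q_k^{1+beta} w(x_i, mu_k, Sigma_k)^{-beta} }^{1/(1+beta)}."""
    X = _as_matrix(X)
    q = _q_values(Q)
    if beta == 0.0:
        pi = q.mean(axis=0)
        return pi / pi.sum()
    W = _powered_weights(Q, beta)
    with np.errstate(divide="ignore"):
        logW = np.log(W, where=W > 0, out=np.full_like(W, -np.inf))
    logw = log_component_weights(X, theta_new, tau, beta)
    t = logsumexp(logW - beta * logw, axis=0) / (1.0 + beta)
    if not np.all(np.isfinite(t)):
        raise EmptyClusterError(int(np.argmax(~np.isfinite(t))))
    pi = np.exp(t - logsumexp(t))
    return pi / pi.sum()


def assign(Q) -> np.ndarray:
    """Hard 1-based labels argmax_k q_k(x_i); ties go to the lowest index."""
    return np.asarray(_q_values(Q).argmax(axis=1) + 1, dtype=int)


# ---------------------------------------------------------------------------
# the fitter
# ---------------------------------------------------------------------------

def _energy(X, theta: ClusterParams, hyper: Hyperparams) -> float:
    if math.isinf(hyper.tau):
        if hyper.beta == 0.0:
            return kmeans_energy(X, theta.centers)
        return fuzzy_energy(X, theta.centers, hyper.beta)
    return pareto_energy(X, theta, hyper.tau, hyper.beta)


def _reseed(X, theta: ClusterParams, hyper: Hyperparams, k: int) -> ClusterParams:
    """Restart component k at the point the current mixture explains worst."""
    X = _as_matrix(X)
    if math.isinf(hyper.tau):
        score = sq_distances(X, theta.centers).min(axis=1)
        worst = int(np.argmax(score))
    else:
        logw = log_component_weights(X, theta, hyper.tau, hyper.beta)
        with np.errstate(divide="ignore"):
            dens = logsumexp(logw + np.log(theta.proportions)[None, :], axis=1)
        worst = int(np.argmin(dens))
    centers = theta.centers.copy()
    centers[k] = X[worst]
    covs = theta.covariances.copy()
    covs[k] = (float(np.var(X)) or 1.0) * np.eye(X.shape[1])
    props = theta.proportions.copy()
    props[k] = 1.0 / theta.n_clusters
    props /= props.sum()
    return ClusterParams(centers, covs, props)


def _sweep(X, theta: ClusterParams, hyper: Hyperparams):
    """One full MM sweep Q -> mu -> Sigma -> pi in the prescribed order."""
    tau, beta = hyper.tau, hyper.beta
    Q = responsibilities(X, theta, tau, beta)
    centers = update_centers(X, Q, beta)
    covs = theta.covariances
    if hyper.estimate_cov:
        covs = update_covariances(X, Q, centers, tau, beta, hyper.ridge_alpha)
    trial = ClusterParams(centers, covs, theta.proportions)
    props = theta.proportions
    if hyper.estimate_pi:
        props = update_proportions(X, Q, trial, tau, beta)
    return ClusterParams(centers, covs, props), Q


def fit(X, K: int, hyper: Hyperparams | None = None,
        init: ClusterParams | None = None) -> FitResult:
    """Fit Pareto clustering to an (n, d) data matrix.

    Iterates full MM sweeps from a Ward-linkage initialization (or ``init``)
    until the relative energy change drops below ``hyper.rel_tol`` or
    ``hyper.max_iter`` sweeps have run.  A component whose membership mass
    vanishes is re-seeded at the worst-explained point; two consecutive
    re-seeds of the same component abort with :class:`ConvergenceError`.
    """
    X = _as_matrix(X)
    hyper = hyper or Hyperparams()
    n, d = X.shape
    if n <= K:
        raise ValueError(f"need n > K, got n={n}, K={K}")
    if math.isinf(hyper.tau):
        if hyper.estimate_cov or hyper.estimate_pi:
            raise ValueError(
                "the tau = inf branch fixes Sigma_k = I and pi_k = 1/K; "
                "set estimate_cov=False and estimate_pi=False"
            )
    elif hyper.estimate_cov and d * hyper.beta >= 2.0:
        raise DegenerateScaleError(
            f"covariance estimation requires d*beta < 2 (d={d}, beta={hyper.beta}); "
            f"lower beta below {2.0 / d:.3g} or set estimate_cov=False"
        )
    theta = init if init is not None else init_params(X, K, ridge_alpha=hyper.ridge_alpha)
    if theta.n_clusters != K or theta.n_features != d:
        raise ValueError("init has the wrong number of clusters or features")

    trace = [_energy(X, theta, hyper)]
    Q = responsibilities(X, theta, hyper.tau, hyper.beta)
    converged = False
    n_reseeds = 0
    last_reseeded = -1
    t = 0
    while t < hyper.max_iter:
        try:
            theta_new, Q = _sweep(X, theta, hyper)
        except EmptyClusterError as err:
            if err.component == last_reseeded:
                raise ConvergenceError(
                    f"component {err.component} stayed empty after re-seeding"
                ) from err
            theta = _reseed(X, theta, hyper, err.component)
            last_reseeded = err.component
            n_reseeds += 1
            trace.append(_energy(X, theta, hyper))
            t += 1
            continue
        last_reseeded = -1
        theta = theta_new
        trace.append(_energy(X, theta, hyper))
        t += 1
        if abs(trace[-2] - trace[-1]) <= hyper.rel_tol * (1.0 + abs(trace[-2])):
            converged = True
            break
    Q = responsibilities(X, theta, hyper.tau, hyper.beta)
    return FitResult(
        params=theta,
        membership=Q,
        labels=assign(Q),
        energy_trace=np.asarray(trace),
        n_iter=t,
        converged=converged,
        n_reseeds=n_reseeds,
    )


# ---------------------------------------------------------------------------
# classic fuzzy c-means (the in-repo equivalence oracle)
# ---------------------------------------------------------------------------

def fcm_reference(X, K: int, m: float, init_centers, max_iter: int = 500,
                  tol: float = 1e-10):
    """Classic (Bezdek) fuzzy c-means fixed-point iteration.

    Memberships follow the row-stochastic convention
    ``u_ik = (d_ik^2)^{-1/(m-1)} / sum_l (d_il^2)^{-1/(m-1)}`` (a point on a
    center gets the full unit membership there), and centers are the
    ``u^m``-weighted means.  Returns ``(centers, memberships)``.
    """
    if not m > 1:
        raise ValueError("fuzzy c-means requires m > 1")
    X = _as_matrix(X)
    centers = _as_matrix(init_centers).copy()
    if centers.shape != (K, X.shape[1]):
        raise ValueError("init_centers must have shape (K, d)")
    beta = m - 1.0
    u = np.exp(_log_q_tau_inf(X, centers, beta))
    for _ in range(max_iter):
        u = np.exp(_log_q_tau_inf(X, centers, beta))
        um = u**m
        denom = um.sum(axis=0)
        if np.any(denom < _DENOM_FLOOR):
            raise EmptyClusterError(int(np.argmin(denom)))
        new_centers = (um.T @ X) / denom[:, None]
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    return centers, u


# ---------------------------------------------------------------------------
# mode presets
# ---------------------------------------------------------------------------

def make_hyperparams(mode: str = "pareto", tau: float | None = None,
                     beta: float | None = None, m: float = 2.0,
                     **kwargs) -> Hyperparams:
    """Hyperparameters for the named regime of the clustering family.

    ``pareto`` (free tau, beta; defaults 0.5, 1), ``gmm`` (beta=0, tau=1/2),
    ``rose`` (beta=0, free tau), ``fuzzy`` (tau=inf, beta=m-1, fixed
    Sigma=I, pi=1/K) and ``kmeans`` (tau=inf, beta=0, fixed Sigma, pi).
    """
    if mode == "pareto":
        return Hyperparams(tau=0.5 if tau is None else tau,
                           beta=1.0 if beta is None else beta, **kwargs)
    if mode == "gmm":
        if beta not in (None, 0.0) or tau not in (None, 0.5):
            raise ValueError("gmm mode fixes beta=0, tau=1/2")
        return Hyperparams(tau=0.5, beta=0.0, **kwargs)
    if mode == "rose":
        if beta not in (None, 0.0):
            raise ValueError("rose mode fixes beta=0")
        kwargs.setdefault("estimate_cov", False)
        kwargs.setdefault("estimate_pi", False)
        return Hyperparams(tau=0.5 if tau is None else tau, beta=0.0, **kwargs)
    if mode == "fuzzy":
        if beta is None:
            beta = m - 1.0
        if not beta > 0:
            raise ValueError("fuzzy mode requires beta = m - 1 > 0")
        kwargs.setdefault("estimate_cov", False)
        kwargs.setdefault("estimate_pi", False)
        return Hyperparams(tau=math.inf, beta=beta, **kwargs)
    if mode == "kmeans":
        kwargs.setdefault("estimate_cov", False)
        kwargs.setdefault("estimate_pi", False)
        return Hyperparams(tau=math.inf, beta=0.0, **kwargs)
    raise ValueError(f"unknown mode {mode!r}")
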