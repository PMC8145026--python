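"""Generalized energy functions (clustering objectives) and their special cases.

The master objective is the Kolmogorov-Nagumo average of per-cluster energies

    L_S(mu) = (1/tau) sum_i S^{-1}( (1/K) sum_k S(tau * ||x_i - mu_k||^2) ),

and, with component covariances Sigma_k and mixing proportions pi_k,

    L_{tau,beta}(theta) = (1/(tau*beta)) sum_i [ ( sum_k pi_k w_ik )^{-beta} - 1 ],
    w_ik = |Sigma_k|^{-1/2} (1 + tau*beta*||x_i-mu_k||^2_{Sigma_k^{-1}})^{-1/beta},

for the generalized Pareto survival function.  Limiting members recover the
familiar objectives: beta -> 0 gives maximum-entropy (Rose) clustering and, at
tau = 1/2, the Gaussian-mixture negative log-likelihood up to n*log((2*pi)^{d/2});
tau -> inf gives fuzzy c-means (beta = m - 1); tau -> inf, beta -> 0 gives
k-means.  All mixture sums are accumulated in log space with max-shift
stabilization, since tau*d^2 easily overflows a naive evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .survival import Family, SurvivalModel

__all__ = [
    "ClusterParams",
    "Hyperparams",
    "component_weight",
    "kn_energy",
    "pareto_energy",
    "rose_energy",
    "fuzzy_energy",
    "kmeans_energy",
    "frechet_energy",
    "frechet_weight",
]

_SIMPLEX_TOL = 1e-10
_SYM_TOL = 1e-10


@dataclass(frozen=True)
class ClusterParams:
    """Mixture parameters theta = (centers mu_k, covariances Sigma_k, proportions pi_k)."""

    centers: np.ndarray
    covariances: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        covs = np.asarray(self.covariances, dtype=float)
        props = np.asarray(self.proportions, dtype=float).ravel()
        K, d = centers.shape
        if covs.shape == (d, d):
            covs = np.broadcast_to(covs, (K, d, d)).copy()
        if covs.shape != (K, d, d):
            raise ValueError(f"covariances must have shape {(K, d, d)}, got {covs.shape}")
        if props.shape != (K,):
            raise ValueError(f"proportions must have length {K}, got {props.shape}")
        if not np.all(np.isfinite(centers)):
            raise ValueError("centers must be finite")
        if np.any(props < 0) or abs(props.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("proportions must be nonnegative and sum to 1")
        for k in range(K):
            if np.max(np.abs(covs[k] - covs[k].T)) > _SYM_TOL * max(1.0, np.max(np.abs(covs[k]))):
                raise ValueError(f"covariance {k} is not symmetric")
            if np.linalg.eigvalsh(covs[k])[0] <= 0:
                raise ValueError(f"covariance {k} is not positive definite")
        for arr in (centers, covs, props):
            arr.setflags(write=False)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "covariances", covs)
        object.__setattr__(self, "proportions", props)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    @classmethod
    def isotropic(cls, centers) -> "ClusterParams":
        """Identity covariances and uniform proportions around the given centers."""
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        K, d = centers.shape
        return cls(centers, np.broadcast_to(np.eye(d), (K, d, d)).copy(), np.full(K, 1.0 / K))


@dataclass(frozen=True)
class Hyperparams:
    """Tuning parameters of the Pareto-clustering fitter.

    ``tau`` sharpens the Kolmogorov-Nagumo average (``math.inf`` selects the
    analytic fuzzy/k-means branch); ``beta`` is the Pareto tail parameter
    (``0`` selects the exponential/Gaussian branch); ``ridge_alpha`` blends
    each covariance update with a scalar matrix, ``alpha = 1`` disabling the
    ridge.  Covariance estimation requires ``d * beta < 2``.
    """

    tau: float = 0.5
    beta: float = 1.0
    estimate_cov: bool = True
    estimate_pi: bool = True
    ridge_alpha: float = 0.95
    max_iter: int = 500
    rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be positive (math.inf selects the analytic branch)")
        if not (self.beta >= 0) or not np.isfinite(self.beta):
            raise ValueError("beta must be finite and nonnegative")
        if not (0 < self.ridge_alpha <= 1):
            raise ValueError("ridge_alpha must lie in (0, 1]")
        if self.max_iter < 1 or self.rel_tol <= 0:
            raise ValueError("max_iter must be >= 1 and rel_tol > 0")


# ---------------------------------------------------------------------------
# distances and component weights
# ---------------------------------------------------------------------------

def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("expected an (n, d) data matrix")
    return X


def sq_distances(X, centers) -> np.ndarray:
    """Pairwise squared Euclidean distances, shape (n, K)."""
    X = _as_matrix(X)
    centers = _as_matrix(centers)
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has d={X.shape[1]}, centers d={centers.shape[1]}"
        )
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def mahalanobis_sq(X, theta: ClusterParams) -> np.ndarray:
    """Squared Mahalanobis distances ||x_i - mu_k||^2_{Sigma_k^{-1}}, shape (n, K)."""
    X = _as_matrix(X)
    n = X.shape[0]
    K = theta.n_clusters
    out = np.empty((n, K))
    for k in range(K):
        try:
            L = np.linalg.cholesky(theta.covariances[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"covariance of component {k} is singular") from exc
        z = np.linalg.solve(L, (X - theta.centers[k]).T)
        out[:, k] = np.einsum("dn,dn->n", z, z)
    return out


def _log_dets(theta: ClusterParams) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(theta.covariances)
    if np.any(sign <= 0):
        k = int(np.argmax(sign <= 0))
        raise np.linalg.LinAlgError(f"covariance of component {k} is not positive definite")
    return logdet


def log_component_weights(X, theta: ClusterParams, tau: float, beta: float) -> np.ndarray:
    """log w(x_i, mu_k, Sigma_k) for all pairs, shape (n, K).

    ``w = |Sigma|^{-1/2} (1 + tau*beta*m)^{-1/beta}`` for ``beta > 0`` and its
    analytic limit ``|Sigma|^{-1/2} exp(-tau*m)`` for ``beta = 0``.
    """
    m = mahalanobis_sq(X, theta)
    logdet = _log_dets(theta)
    if beta == 0.0:
        core = -tau * m
    else:
        core = -np.log1p(tau * beta * m) / beta
    return core - 0.5 * logdet[None, :]


def component_weight(x, mu, sigma, tau: float, beta: float):
    """The component weight w(x, mu, Sigma) of a single mixture component."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    theta = ClusterParams(mu[None, :], sigma[None, :, :], np.array([1.0]))
    w = np.exp(log_component_weights(x, theta, tau, beta)[:, 0])
    return w[0] if w.size == 1 else w


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def kn_energy(X, centers, model: SurvivalModel, tau: float) -> float:
    """The center-only Kolmogorov-Nagumo energy for an arbitrary survival family.

    Evaluated through family-specific log-space identities so that extreme
    ``tau`` (used by the limit checks) neither overflows nor underflows.  For
    ``K = 1`` the composition ``S^{-1}(S(.))`` cancels and the value is exactly
    the summed squared distance.
    """
    d2 = sq_distances(X, centers)
    K = d2.shape[1]
    t = tau * d2
    if model.is_exponential_branch:
        # (1/tau) sum_i -log mean_k exp(-t) : a stabilized soft-min.
        val = -(logsumexp(-t, axis=1) - math.log(K))
        return float(val.sum() / tau)
    if model.family is Family.PARETO:
        beta = model.shape
        logS = -np.log1p(beta * t) / beta
        logmean = logsumexp(logS, axis=1) - math.log(K)
        val = np.expm1(-beta * logmean) / beta
        return float(val.sum() / tau)
    # Frechet: S = 1 - exp(-t^gamma); mean_k S = 1 - mean_k exp(-t^gamma) and
    # S^{-1}(u) = (-log(1-u))^{1/gamma}, so only 1 - mean is ever formed.
    gamma = model.shape
    with np.errstate(divide="ignore"):
        tg = np.where(t > 0, np.power(np.where(t > 0, t, 1.0), gamma), np.inf)
    logm = logsumexp(-tg, axis=1) - math.log(K)
    val = np.power(-logm, 1.0 / gamma)
    return float(val.sum() / tau)


def pareto_energy(X, theta: ClusterParams, tau: float, beta: float) -> float:
    """The full Pareto objective L_{tau,beta}(theta); beta = 0 dispatches to
    :func:`rose_energy` (its analytic limit)."""
    if beta == 0.0:
        return rose_energy(X, theta, tau)
    logw = log_component_weights(X, theta, tau, beta)
    with np.errstate(divide="ignore"):
        logs = logsumexp(logw + np.log(theta.proportions)[None, :], axis=1)
    val = np.expm1(-beta * logs).sum() / (tau * beta)
    if not np.isfinite(val):
        raise FloatingPointError("pareto_energy produced a non-finite value")
    return float(val)


def rose_energy(X, theta: ClusterParams, tau: float) -> float:
    """Maximum-entropy (Rose) objective, the beta -> 0 member of the family.

    At ``tau = 1/2`` this is the Gaussian-mixture negative log-likelihood minus
    the constant ``n * log((2*pi)^{d/2})``.
    """
    logw = log_component_weights(X, theta, tau, 0.0)
    with np.errstate(divide="ignore"):
        logs = logsumexp(logw + np.log(theta.proportions)[None, :], axis=1)
    return float(-logs.sum() / tau)


def fuzzy_energy(X, centers, beta: float) -> float:
    """The tau -> inf member: sum_i [ (1/K) sum_k (d_ik^2)^{-1/beta} ]^{-beta}.

    A point that coincides with a center contributes its analytic limit 0 (the
    zero distance dominates the Kolmogorov-Nagumo average), matching the
    k-means / fuzzy c-means convention for zero distances.
    """
    if not beta > 0:
        raise ValueError("fuzzy_energy requires beta > 0")
    d2 = sq_distances(X, centers)
    K = d2.shape[1]
    hit = np.any(d2 == 0.0, axis=1)
    safe = np.where(d2 == 0.0, 1.0, d2)
    inner = logsumexp(-np.log(safe) / beta, axis=1) - math.log(K)
    val = np.where(hit, 0.0, np.exp(-beta * inner))
    return float(val.sum())


def kmeans_energy(X, centers) -> float:
    """Sum of squared distances to the nearest center (Lloyd's objective)."""
    return float(sq_distances(X, centers).min(axis=1).sum())


def _frechet_parts(X, centers, tau: float, gamma: float):
    if gamma >= 0:
        raise ValueError("frechet requires gamma < 0")
    if not tau > 0:
        raise ValueError("tau must be positive")
    d2 = sq_distances(X, centers)
    s = tau**gamma
    with np.errstate(divide="ignore"):
        a = np.where(d2 > 0, np.power(np.where(d2 > 0, d2, 1.0), gamma), np.inf)
    K = d2.shape[1]
    logm = logsumexp(-s * a, axis=1) - math.log(K)  # log mean_k exp(-tau^g * (d^2)^g)
    return d2, a, s, logm


def frechet_energy(X, centers, tau: float, gamma: float) -> float:
    """The Frechet-family energy L_{gamma,tau}(mu).

    For ``K = 1`` the powers cancel and the value is the summed squared
    distance.  As ``tau -> inf`` it tends to :func:`fuzzy_energy` with
    ``beta = -1/gamma``; as ``tau -> 0`` it tends to the *max*-distance sum
    ``sum_i max_k d_ik^2`` (the sharpened average is dominated by the farthest
    center, because the inner soft-min acts on (d^2)^gamma with gamma < 0).
    """
    _, _, _, logm = _frechet_parts(X, centers, tau, gamma)
    val = np.power(-logm, 1.0 / gamma).sum() / tau
    return float(val)


def frechet_weight(x, centers, k: int, tau: float, gamma: float):
    """The estimating-equation weight omega_k(x, tau, gamma) of the Frechet energy.

    Defined so that ``grad_{mu_k} L = 2 sum_i omega_k(x_i) (mu_k - x_i)``
    (derived directly from :func:`frechet_energy`; verified against numerical
    differentiation in the tests).  Nonnegative; equidistant points weight all
    centers equally, and as the average sharpens the weight concentrates on a
    single center per point.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d2, a, s, logm = _frechet_parts(x, centers, tau, gamma)
    B = -logm / s
    soft = np.exp(-s * a - logsumexp(-s * a, axis=1, keepdims=True))
    with np.errstate(divide="ignore", over="ignore"):
        w = np.power(B, 1.0 / gamma - 1.0) * soft[:, k] * np.power(
            np.where(d2[:, k] > 0, d2[:, k], 1.0), gamma - 1.0
        )
    w = np.where(d2[:, k] > 0, w, 0.0)
    return float(w[0]) if w.size == 1 else w
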