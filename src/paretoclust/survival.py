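"""Survival-function families underlying the generalized energy objective.

The clustering objectives in this package are built from a Kolmogorov-Nagumo
(quasi-arithmetic) average ``S^{-1}((1/K) sum_k S(tau * d_k^2))`` of per-cluster
squared distances, where ``S`` is the survival function of a nonnegative random
variable.  Three families are supported:

* ``pareto`` -- generalized Pareto, ``S(t) = (1 + beta*t)^(-1/beta)`` with shape
  ``beta > 0``.  The tail parameter ``beta`` interpolates between the Gaussian
  mixture regime (``beta -> 0``) and fuzzy c-means (``tau -> inf``).
* ``exponential`` -- ``S(t) = exp(-t)``, the ``beta -> 0`` limit of the Pareto
  family; it generates maximum-entropy (deterministic annealing) clustering.
* ``frechet`` -- ``S(t) = 1 - exp(-t^gamma)`` with shape ``gamma < 0``.

``beta = 0`` is accepted as an exact alias for the exponential branch: the
Pareto formulas are evaluated through ``log1p``/``expm1`` identities, which are
stable for small ``beta`` and large ``t``, and the analytic ``beta = 0`` branch
avoids the 0/0 form entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class Family(str, enum.Enum):
    PARETO = "pareto"
    EXPONENTIAL = "exponential"
    FRECHET = "frechet"


@dataclass(frozen=True)
class SurvivalModel:
    """A survival-function family together with its shape parameter.

    Parameters
    ----------
    family
        One of ``"pareto"``, ``"exponential"``, ``"frechet"`` (or a
        :class:`Family` member).
    shape
        ``beta`` for the Pareto family (``beta > 0``; ``beta = 0`` is accepted
        as an exact alias for the exponential family), ``gamma < 0`` for the
        Frechet family, ignored for the exponential family.
    """

    family: Family
    shape: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        shape = float(self.shape)
        object.__setattr__(self, "shape", shape)
        if self.family is Family.PARETO and shape < 0:
            raise ValueError(f"pareto shape must satisfy beta >= 0, got {shape}")
        if self.family is Family.FRECHET and shape >= 0:
            raise ValueError(f"frechet shape must satisfy gamma < 0, got {shape}")
        if not np.isfinite(shape):
            raise ValueError("shape must be finite")

    @property
    def is_exponential_branch(self) -> bool:
        """True when the model evaluates through exp/log (exponential or beta=0)."""
        return self.family is Family.EXPONENTIAL or (
            self.family is Family.PARETO and self.shape == 0.0
        )


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival functions are defined on t >= 0")
    return t


def survival(model: SurvivalModel, t):
    """Evaluate ``S(t)`` elementwise; ``S(0) = 1`` and ``S`` is decreasing."""
    t = _check_t(t)
    if model.is_exponential_branch:
        return np.exp(-t)
    if model.family is Family.PARETO:
        beta = model.shape
        return np.exp(-np.log1p(beta * t) / beta)
    # Frechet: 1 - exp(-t^gamma), gamma < 0; t = 0 gives t^gamma = +inf -> S = 1.
    gamma = model.shape
    with np.errstate(divide="ignore"):
        tg = np.where(t > 0, np.power(np.where(t > 0, t, 1.0), gamma), np.inf)
    return -np.expm1(-tg)


def survival_inv(model: SurvivalModel, u):
    """Evaluate ``S^{-1}(u)``.

    For the Pareto/exponential families the convex formula extends beyond
    ``u = 1`` (values in ``(1, inf)`` map to negative energies), which the
    covariance-weighted objective relies on.  The Frechet inverse is only
    defined on ``(0, 1)``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("survival_inv requires u > 0")
    if model.is_exponential_branch:
        return -np.log(u)
    if model.family is Family.PARETO:
        beta = model.shape
        # (u^-beta - 1)/beta via expm1 to avoid cancellation at small beta.
        return np.expm1(-beta * np.log(u)) / beta
    gamma = model.shape
    if np.any(u >= 1):
        raise ValueError("frechet survival_inv requires u in (0, 1)")
    return np.power(-np.log1p(-u), 1.0 / gamma)


def density(model: SurvivalModel, t):
    """The density ``f(t) = -dS/dt`` of the family, elementwise on ``t >= 0``."""
    t = _check_t(t)
    if model.is_exponential_branch:
        return np.exp(-t)
    if model.family is Family.PARETO:
        beta = model.shape
        return np.exp(-(1.0 / beta + 1.0) * np.log1p(beta * t))
    # Frechet: f(t) = -gamma * t^(gamma-1) * exp(-t^gamma); the essential
    # singularity exp(-t^gamma) -> 0 dominates every power as t -> 0+, so the
    # limit at t = 0 is 0 for every gamma < 0.
    gamma = model.shape
    pos = t > 0
    tpos = np.where(pos, t, 1.0)
    f = np.where(pos, -gamma * np.power(tpos, gamma - 1.0) * np.exp(-np.power(tpos, gamma)), 0.0)
    return f
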