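"""External cluster-validation metrics: precision/recall, Purity, F-value,
the Centroid Index, and matched center MSE.

Purity weights the best per-cluster precision by cluster size; the F-value
weights the best per-class harmonic mean of precision and recall by class
size.  The Centroid Index (CI) is a cluster-level integer dissimilarity: it
counts reference centers that are not the nearest reference of any estimated
center ("orphans"), symmetrized by taking the maximum over the two
directions.  Center MSE is the mean squared distance between estimated and
reference centers after a minimum-cost bipartite (Hungarian) matching --
fitted components come back in arbitrary order, and the matching is the only
label-invariant way to pair them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LabeledPartition",
    "CenterSet",
    "precision_recall",
    "purity",
    "f_value",
    "centroid_index",
    "mse_centers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledPartition:
    """A hard partition: integer labels in {1, ..., n_groups}."""

    labels: np.ndarray
    n_groups: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-d integer vector")
        if labels.size and (labels.min() < 1 or labels.max() > self.n_groups):
            raise ValueError("labels must lie in {1, ..., n_groups}")
        labels = labels.copy()
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_labels(cls, labels) -> "LabeledPartition":
        """Build from arbitrary integer labels, remapped to 1..L by sorted value."""
        labels = np.asarray(labels, dtype=int)
        uniq, remapped = np.unique(labels, return_inverse=True)
        return cls(remapped + 1, len(uniq))


@dataclass(frozen=True)
class CenterSet:
    """A finite set of centers, one per row."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0 or not np.all(np.isfinite(centers)):
            raise ValueError("centers must be a nonempty finite matrix")
        centers = centers.copy()
        centers.setflags(write=False)
        object.__setattr__(self, "centers", centers)


def _as_partition(p) -> LabeledPartition:
    return p if isinstance(p, LabeledPartition) else LabeledPartition.from_labels(p)


def _as_centers(c) -> np.ndarray:
    return c.centers if isinstance(c, CenterSet) else np.atleast_2d(np.asarray(c, dtype=float))


def _contingency(C: LabeledPartition, D: LabeledPartition) -> np.ndarray:
    if C.labels.shape != D.labels.shape:
        raise ValueError("partitions must label the same points")
    table = np.zeros((C.n_groups, D.n_groups), dtype=int)
    np.add.at(table, (C.labels - 1, D.labels - 1), 1)
    return table


def _drop_empty(table: np.ndarray, axis: int, what: str) -> np.ndarray:
    sizes = table.sum(axis=1 - axis)
    if np.any(sizes == 0):
        logger.warning("dropping %d empty %s before scoring", int((sizes == 0).sum()), what)
        table = np.compress(sizes > 0, table, axis=axis)
    return table


def precision_recall(C, D, k: int, l: int) -> tuple[float, float]:
    """Precision |C_k intersect D_l| / |C_k| and recall |...| / |D_l| (1-based k, l)."""
    C, D = _as_partition(C), _as_partition(D)
    table = _contingency(C, D)
    ck = table[k - 1].sum()
    dl = table[:, l - 1].sum()
    if ck == 0:
        raise ValueError(f"cluster {k} is empty; precision is undefined")
    if dl == 0:
        raise ValueError(f"class {l} is empty; recall is undefined")
    inter = table[k - 1, l - 1]
    return inter / ck, inter / dl


def purity(C, D) -> float:
    """Size-weighted best per-cluster precision against the reference classes."""
    C, D = _as_partition(C), _as_partition(D)
    table = _drop_empty(_contingency(C, D), axis=0, what="clusters")
    n = table.sum()
    return float(table.max(axis=1).sum() / n)


def f_value(C, D) -> float:
    """Size-weighted best per-class F-measure against the clusters.

    The outer sum runs over reference classes, with the best harmonic mean of
    precision and recall over clusters.
    """
    C, D = _as_partition(C), _as_partition(D)
    table = _drop_empty(_contingency(C, D), axis=0, what="clusters")
    n = table.sum()
    class_sizes = table.sum(axis=0)      # |D_k|
    cluster_sizes = table.sum(axis=1)    # |C_l|
    prec = table.T / class_sizes[:, None]        # Precision(D_k, C_l) = |inter| / |D_k|
    rec = table.T / cluster_sizes[None, :]       # Recall(D_k, C_l) = |inter| / |C_l|
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float((class_sizes / n * f.max(axis=1)).sum())


def _orphans(A: np.ndarray, B: np.ndarray) -> int:
    """Number of rows of B that are nearest (in B) to no row of A."""
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)  # ties -> lowest index, deterministic
    covered = np.zeros(B.shape[0], dtype=bool)
    covered[nearest] = True
    return int((~covered).sum())


def centroid_index(mu_hat, mu_star) -> int:
    """CI = max(CI'(mu_hat, mu_star), CI'(mu_star, mu_hat)); 0 iff the
    nearest-neighbor map covers every center in both directions."""
    A, B = _as_centers(mu_hat), _as_centers(mu_star)
    if A.shape[1] != B.shape[1]:
        raise ValueError("center sets must share the dimension")
    return max(_orphans(A, B), _orphans(B, A))


def mse_centers(mu_hat, mu_star) -> float:
    """Mean squared center error (1/K) sum_k ||mu_hat_k - mu_star_k||^2 under
    the minimum-cost bipartite matching of the two sets."""
    A, B = _as_centers(mu_hat), _as_centers(mu_star)
    if A.shape != B.shape:
        raise ValueError(f"center sets must match in shape, got {A.shape} vs {B.shape}")
    cost = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / A.shape[0])
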