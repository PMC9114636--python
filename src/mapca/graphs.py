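"""k-nearest-neighbor graphs with Gaussian edge weights and local weighted means.

The local weighted mean (LWM) of an instance is the convex combination of its
k nearest neighbors with weights ``exp(-tau * ||x_i - x_j||^2)``, normalized
over the neighbor set.  The LWM acts as a smoothed stand-in for the instance:
the classifier is asked to produce consistent outputs for a point and for the
weighted center of its neighborhood, which is what couples the labeled and
unlabeled parts of the sample through the data manifold.

Conventions
-----------
* Neighbors are found by exact Euclidean distance; ties at the k-th distance
  are broken toward the lowest instance index (stable argsort).
* An instance is never its own neighbor.
* The stored weight matrix ``D`` is symmetrized with the elementwise maximum
  of the two directed assignments; the LWM, however, uses the *directed*
  neighbor set of each instance, matching the one-sided sum that defines it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .exceptions import DegenerateGraphError, InputError, ParameterError

__all__ = ["NeighborGraph", "build_graph", "local_weighted_mean", "median_heuristic_tau"]


@dataclass(frozen=True)
class NeighborGraph:
    """A k-NN graph with Gaussian edge weights.

    Attributes
    ----------
    n : int
        Number of instances.
    k : int
        Neighbors per instance.
    tau : float
        Gaussian width; edge weight is ``exp(-tau * squared distance)``.
    neighbor_index : ndarray of shape (n, k)
        Row i lists the 0-based indices of the k nearest neighbors of
        instance i (self excluded), nearest first.
    D : ndarray of shape (n, n)
        Symmetric nonnegative weight matrix; ``D[i, j] > 0`` iff j is a
        neighbor of i or i is a neighbor of j.
    """

    n: int
    k: int
    tau: float
    neighbor_index: np.ndarray
    D: np.ndarray


def median_heuristic_tau(X: np.ndarray) -> float:
    """Scale-robust default width: ``1 / (2 * median pairwise squared distance)``.

    Falls back to 1.0 when the median squared distance is zero (all points
    coincident), where any width gives the same unit weights.
    """
    X = np.asarray(X, dtype=float)
    d2 = pdist(X, "sqeuclidean")
    med = float(np.median(d2)) if d2.size else 0.0
    if med <= 0.0:
        return 1.0
    return 1.0 / (2.0 * med)


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError(f"feature matrix must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError("feature matrix contains non-finite entries")
    return X


def build_graph(X: np.ndarray, k: int, tau: float | None = None) -> NeighborGraph:
    """Build the k-NN graph with Gaussian weights on the squared distances.

    Parameters
    ----------
    X : (n, d) array
        Feature matrix, one row per instance.
    k : int
        Number of neighbors; requires ``n >= k + 1``.
    tau : float, optional
        Gaussian width (> 0).  Defaults to the median heuristic.

    Returns
    -------
    NeighborGraph
        ``D[i, j] = exp(-tau * ||x_i - x_j||^2)`` whenever j is a neighbor of
        i or i a neighbor of j (symmetrized), else 0.
    """
    X = _check_features(X)
    n = X.shape[0]
    k = int(k)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ParameterError(f"need n >= k + 1 instances, got n={n}, k={k}")
    if tau is None:
        tau = median_heuristic_tau(X)
    tau = float(tau)
    if not (tau > 0 and np.isfinite(tau)):
        raise ParameterError(f"tau must be a positive finite real, got {tau}")

    dist2 = cdist(X, X, "sqeuclidean")
    # Stable argsort: equal distances keep the lowest index first, which is
    # the documented deterministic tie-break.
    order = np.argsort(dist2, axis=1, kind="stable")
    neighbor_index = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        row = order[i]
        neighbor_index[i] = row[row != i][:k]

    weights = np.exp(-tau * dist2)
    directed = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    cols = neighbor_index.ravel()
    directed[rows, cols] = weights[rows, cols]
    D = np.maximum(directed, directed.T)
    return NeighborGraph(n=n, k=k, tau=tau, neighbor_index=neighbor_index, D=D)


def local_weighted_mean(X: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Compute the LWM of every instance over its directed neighbor set.

    Row i of the result is the convex combination of instance i's neighbors
    with weights ``D[i, j] / sum_j D[i, j]``, j ranging over the k nearest
    neighbors of i.

    Raises
    ------
    DegenerateGraphError
        If some row's neighbor weights underflowed to zero; reduce ``tau``.
    """
    X = _check_features(X)
    if X.shape[0] != graph.n:
        raise InputError(
            f"feature matrix has {X.shape[0]} rows but graph was built on {graph.n}"
        )
    idx = graph.neighbor_index
    w = graph.D[np.arange(graph.n)[:, None], idx]
    totals = w.sum(axis=1)
    if np.any(totals <= 0.0):
        bad = int(np.flatnonzero(totals <= 0.0)[0])
        raise DegenerateGraphError(
            f"instance {bad} has all-zero neighbor weights (exp underflow); "
            "reduce tau so that exp(-tau * d^2) stays positive"
        )
    return (w[:, :, None] * X[idx]).sum(axis=1) / totals[:, None]
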