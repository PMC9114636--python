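"""Kernel functions, Gram matrices and multi-kernel concatenation.

Four translation-invariant kernel families are supported, all bounded in
(0, 1] with unit value at zero distance (r = Euclidean distance, sigma > 0):

==========================  =========================
family                      k(a, b)
==========================  =========================
``gaussian``                ``exp(-sigma * r**2)``
``inverse_square_distance`` ``1 / (1 + sigma * r**2)``
``laplacian``               ``exp(-sigma * r)``
``inverse_distance``        ``1 / (1 + sigma * r)``
==========================  =========================

All four are positive semidefinite (the inverse families are scale mixtures
of the Gaussian / Laplacian family respectively), so any sum of them is a
valid kernel.  Multi-kernel learning concatenates the feature maps of several
kernels; because inner products are additive across concatenated blocks, the
effective Gram matrix is simply the sum of the per-kernel Gram matrices, and
every solver shape is unchanged.

When ``sigma`` is left unset it defaults to ``1/d`` with ``d`` the feature
dimension, the standard width for these features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InputError, ParameterError

__all__ = [
    "FAMILIES",
    "KernelSpec",
    "GramPair",
    "gram",
    "gram_pair",
    "stack_kernels",
    "default_multi_kernel",
]

FAMILIES = ("gaussian", "inverse_square_distance", "laplacian", "inverse_distance")

_SQUARED = {"gaussian", "inverse_square_distance"}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus width.

    ``sigma=None`` means "resolve to 1/d when the data dimension is known".
    """

    family: str = "gaussian"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown kernel family {self.family!r}; choose one of {FAMILIES}"
            )
        if self.sigma is not None and not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ParameterError(f"sigma must be positive and finite, got {self.sigma}")

    def resolved(self, d: int) -> "KernelSpec":
        """Return a spec with ``sigma`` fixed, defaulting to ``1/d``."""
        if self.sigma is not None:
            return self
        return replace(self, sigma=1.0 / float(d))


@dataclass(frozen=True)
class GramPair:
    """Gram matrix on samples plus the cross-Gram against their LWM points.

    ``K[i, j] = k(x_i, x_j)`` and ``Kbar[i, j] = k(xhat_i, x_j)``.
    """

    K: np.ndarray
    Kbar: np.ndarray


def _check(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise InputError(f"{name} must be 2-D, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InputError(f"{name} contains non-finite entries")
    return A


def gram(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix ``k(a_i, b_j)`` of shape (p, q)."""
    A = _check(A, "A")
    B = _check(B, "B")
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}"
        )
    sigma = spec.resolved(A.shape[1]).sigma
    if spec.family in _SQUARED:
        r = cdist(A, B, "sqeuclidean")
    else:
        r = cdist(A, B, "euclidean")
    if spec.family in ("gaussian", "laplacian"):
        return np.exp(-sigma * r)
    return 1.0 / (1.0 + sigma * r)


def _as_specs(specs: KernelSpec | Iterable[KernelSpec]) -> tuple[KernelSpec, ...]:
    if isinstance(specs, KernelSpec):
        return (specs,)
    out = tuple(specs)
    if not out:
        raise ParameterError("at least one kernel spec is required")
    if not all(isinstance(s, KernelSpec) for s in out):
        raise ParameterError("kernel specs must be KernelSpec instances")
    return out


def gram_pair(
    X: np.ndarray, Xhat: np.ndarray, specs: KernelSpec | Sequence[KernelSpec]
) -> GramPair:
    """Effective (possibly multi-kernel) Gram and cross-Gram matrices.

    With several specs the result is the sum of the member Gram matrices,
    which realizes the concatenated feature space exactly.
    """
    specs = _as_specs(specs)
    K = sum(gram(X, X, s) for s in specs)
    Kbar = sum(gram(Xhat, X, s) for s in specs)
    return GramPair(K=np.asarray(K), Kbar=np.asarray(Kbar))


def stack_kernels(
    specs: Sequence[KernelSpec], X: np.ndarray, Xhat: np.ndarray
) -> GramPair:
    """Concatenate kernel feature spaces; alias of :func:`gram_pair`."""
    return gram_pair(X, Xhat, specs)


def default_multi_kernel(sigma: float | None = None) -> tuple[KernelSpec, ...]:
    """The four-family kernel bank with a shared width (default 1/d)."""
    return tuple(KernelSpec(family=f, sigma=sigma) for f in FAMILIES)
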