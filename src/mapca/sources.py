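"""Source models: training, projection onto the target sample, and weighting.

A source model is a pre-trained classifier expressed as dual coefficients
over a reference sample, ``f_s(x) = alpha_s^T k(x)``.  The adaptation terms
multiply source and target models against the *target* Gram matrices, so a
model trained on its own domain is re-expressed over the target sample by
kernel least squares: its decision values on the target points are computed
and projected back through the target Gram matrix.

Weighting schemes for fusing several sources:

* ``optimal``  — the simplex-constrained quadratic program over the model
  discrepancies (delegates to :func:`mapca.solver.update_gamma`);
* ``uniform``  — ``gamma_i = 1/q`` (the mean-fusion ablation);
* ``distance`` — softmax of ``-delta * Dist(X_i^s, X)`` with Dist the kernel
  maximum mean discrepancy (squared) between domains;
* ``fixed``    — user-supplied weights, validated against the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, solve

from .exceptions import InputError, ParameterError, SingularSystemError
from .graphs import build_graph, local_weighted_mean
from .kernels import KernelSpec, gram, gram_pair
from . import solver as _solver
from .solver import Hyperparams, LabelEncoding, make_problem, update_alpha

__all__ = [
    "SourceModel",
    "WeightingScheme",
    "train_source",
    "project_model",
    "domain_distance",
    "make_weights",
    "fuse_decision_values",
]

WEIGHTING_MODES = ("optimal", "uniform", "distance", "fixed")


@dataclass(frozen=True)
class SourceModel:
    """A classifier as dual coefficients over a reference sample.

    ``origin`` records whether the model was trained directly on the stored
    sample ("trained-here") or re-expressed by projection ("projected").
    """

    alpha: np.ndarray          # (n, M)
    X: np.ndarray              # (n, d) reference sample
    kernels: tuple[KernelSpec, ...]
    classes: np.ndarray
    origin: str = "trained-here"
    name: str | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.alpha)):
            raise InputError("source model coefficients contain non-finite entries")
        if self.alpha.shape[0] != self.X.shape[0]:
            raise InputError("alpha rows must match the reference sample size")

    def decision_values(self, Xq: np.ndarray) -> np.ndarray:
        Kq = sum(gram(np.asarray(Xq, float), self.X, s) for s in self.kernels)
        return Kq @ self.alpha


@dataclass(frozen=True)
class WeightingScheme:
    """How source weights are produced; see the module docstring."""

    mode: str = "optimal"
    delta: float = 100.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in WEIGHTING_MODES:
            raise ParameterError(
                f"mode must be one of {WEIGHTING_MODES}, got {self.mode!r}"
            )
        if not (self.delta > 0 and np.isfinite(self.delta)):
            raise ParameterError(f"delta must be > 0, got {self.delta}")


def train_source(
    X_source: np.ndarray,
    y_source: np.ndarray,
    hp: Hyperparams | None = None,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
    k: int = 5,
    tau: float | None = None,
    name: str | None = None,
) -> SourceModel:
    """Fit a kernel least-squares classifier on a fully labeled source domain.

    This is the unlabeled-free, adaptation-free special case of the target
    solver's alpha update (one closed-form solve, including the LWM
    consistency terms), yielding dual coefficients over the source sample.
    """
    hp = hp or Hyperparams()
    X_source = np.asarray(X_source, dtype=float)
    y_source = np.asarray(y_source)
    if np.any(y_source < 0):
        raise InputError("source domains must be fully labeled")
    encoding = LabelEncoding(classes=np.unique(y_source))
    graph = build_graph(X_source, k=k, tau=tau)
    Xhat = local_weighted_mean(X_source, graph)
    specs = _solver._normalize_kernels(kernels, X_source.shape[1])
    grams = gram_pair(X_source, Xhat, specs)
    Y = encoding.one_hot(y_source)
    prob = make_problem(
        grams,
        labeled=np.ones(len(y_source), dtype=bool),
        Y=Y,
        centers=encoding.centers,
        source_alphas=np.zeros((0, len(y_source), encoding.M)),
        hp=replace(hp, beta=0.0),
    )
    alpha = update_alpha(np.zeros_like(Y), np.zeros(0), prob)
    return SourceModel(
        alpha=alpha, X=X_source, kernels=specs, classes=encoding.classes,
        origin="trained-here", name=name,
    )


def project_model(model: SourceModel, X_target: np.ndarray) -> SourceModel:
    """Re-express a source model as dual coefficients over the target sample.

    The model's decision values on the target points are projected through
    the target Gram matrix: ``alpha_t = (K_tt + jitter I)^{-1} F`` with a
    tiny ridge jitter ``1e-10 tr(K)/n`` for conditioning.  Projecting a model
    that already lives on the target sample is idempotent (up to the jitter).
    """
    X_target = np.asarray(X_target, dtype=float)
    if X_target.shape[1] != model.X.shape[1]:
        raise InputError("source and target feature dimensions differ")
    F = model.decision_values(X_target)
    K = sum(gram(X_target, X_target, s) for s in model.kernels)
    try:
        alpha = solve(K, F, assume_a="pos")
    except LinAlgError:
        jitter = 1e-10 * np.trace(K) / K.shape[0]
        try:
            alpha = solve(K + jitter * np.eye(K.shape[0]), F, assume_a="pos")
        except LinAlgError as exc:  # pragma: no cover
            raise SingularSystemError("target Gram matrix is singular") from exc
    return SourceModel(
        alpha=alpha, X=X_target, kernels=model.kernels, classes=model.classes,
        origin="projected", name=model.name,
    )


def domain_distance(
    X_source: np.ndarray,
    X_target: np.ndarray,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
) -> float:
    """Squared kernel maximum mean discrepancy between two domains.

    Biased (V-statistic) estimator: ``mean K_ss + mean K_tt - 2 mean K_st``;
    nonnegative for positive semidefinite kernels, zero for identical
    samples, and symmetric in its arguments.
    """
    Xs = np.asarray(X_source, dtype=float)
    Xt = np.asarray(X_target, dtype=float)
    if Xs.size == 0 or Xt.size == 0:
        raise InputError("domain_distance requires nonempty domains")
    if Xs.shape[1] != Xt.shape[1]:
        raise InputError("domains must share the feature dimension")
    specs = _solver._normalize_kernels(kernels, Xs.shape[1])
    mmd2 = 0.0
    for s in specs:
        mmd2 += (
            float(gram(Xs, Xs, s).mean())
            + float(gram(Xt, Xt, s).mean())
            - 2.0 * float(gram(Xs, Xt, s).mean())
        )
    return max(mmd2, 0.0)


def make_weights(
    scheme: WeightingScheme,
    values: np.ndarray | None = None,
    eta: float = 1.0,
) -> np.ndarray:
    """Produce simplex weights for q sources under the given scheme.

    ``values`` are model discrepancies (optimal mode) or domain distances
    (uniform / distance modes; uniform only uses their count).
    """
    if scheme.mode == "fixed":
        if scheme.weights is None:
            raise ParameterError("fixed mode requires scheme.weights")
        w = np.asarray(scheme.weights, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ParameterError("fixed weights must lie on the probability simplex")
        return w / w.sum()
    if values is None:
        raise ParameterError(f"{scheme.mode} mode requires per-source values")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ParameterError("values must be a nonempty 1-D array")
    q = values.size
    if scheme.mode == "uniform":
        return np.full(q, 1.0 / q)
    if scheme.mode == "distance":
        z = -scheme.delta * values
        z -= z.max()  # stable softmax
        e = np.exp(z)
        return e / e.sum()
    return _solver.update_gamma(values, eta)


def fuse_decision_values(decision_list: Sequence[np.ndarray]) -> np.ndarray:
    """Unweighted mean of decision values from several classifiers.

    The no-adaptation baseline: classifiers trained independently on each
    domain's labeled data are fused by equally averaging their decision
    values on the target points.
    """
    if not decision_list:
        raise ParameterError("need at least one decision-value matrix to fuse")
    stack = np.stack([np.asarray(F, dtype=float) for F in decision_list])
    return stack.mean(axis=0)
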