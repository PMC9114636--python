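"""Alternating optimization for multi-model adaptation with possibilistic clustering.

The model classifies a partially labeled sample by minimizing, over a dual
coefficient matrix ``alpha`` (the decision function is
``f(x) = alpha^T k(x)`` by the representer expansion), per-class possibilistic
memberships ``v_m(x_j)`` of the unlabeled instances, and simplex-constrained
source weights ``gamma``, the objective

    Q(alpha, V, gamma) =
        sum_{i labeled}   ||f(x_i)    - y_i||^2
      + lambda_s * sum_{i labeled} ||f(xhat_i) - y_i||^2
      + sum_m sum_{j unlabeled} v_mj^2 * ||f(x_j)    - c_m||^2
      + lambda_s * sum_m sum_j  v_mj^2 * ||f(xhat_j) - c_m||^2
      + lam * tr(alpha^T K alpha)
      + C * sum_m sum_j (v_mj^2 ln v_mj^2 - v_mj^2)
      + beta * ( sum_i gamma_i A_i(alpha) + eta * ||gamma||^2 )

where ``xhat`` is the local weighted mean of an instance, ``c_m`` are the
class prototypes (one-hot basis vectors in label space), and
``A_i = (1/n) ||K (alpha - alpha_i^s)||_F^2`` measures the divergence of the
target model from the i-th pre-trained source model expressed over the same
reference sample (the empirical, scatter-weighted form of the model
discrepancy; an identity-divergence variant ``(1/n)||alpha - alpha_i^s||_F^2``
is available for ablation).

Each block update is an exact minimizer of its coordinate subproblem:

* ``alpha``: solution of the normal equations ``H alpha = B`` obtained by
  differentiating Q;
* ``V``:   closed form ``v = exp(-(d^2 + lambda_s * dhat^2) / (2C))`` from
  the fuzzy-entropy stationarity condition — memberships are per-class and
  unnormalized, so outliers can be "none of the above";
* ``gamma``: pairwise coordinate descent on the simplex-constrained quadratic
  program ``min gamma^T A + eta ||gamma||^2``.

Consequently the objective is non-increasing across every partial update and
full cycle; a window-based criterion stops the iteration once the relative
spread of the last few objective values falls below ``eps``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, solve
from scipy.spatial.distance import cdist

from .exceptions import (
    DescentDiagnosticError,
    InputError,
    ParameterError,
    SingularSystemError,
)
from .graphs import build_graph, local_weighted_mean
from .kernels import GramPair, KernelSpec, gram, gram_pair

logger = logging.getLogger("mapca.solver")

__all__ = [
    "Hyperparams",
    "LabelEncoding",
    "Problem",
    "SolverState",
    "FitResult",
    "Prediction",
    "make_problem",
    "normal_equations",
    "objective",
    "update_alpha",
    "update_membership",
    "adaptation_scores",
    "update_gamma",
    "fit",
    "fit_sspca",
    "predict",
    "decision_values",
    "labels_from_decisions",
]

_MEMBERSHIP_FLOOR = 1e-300
_DESCENT_RTOL = 1e-9

DIVERGENCES = ("target_scatter", "identity")


@dataclass(frozen=True)
class Hyperparams:
    """Weights and control parameters of the objective.

    Parameters
    ----------
    lam : float
        RKHS norm weight (> 0); larger values shrink the decision function.
    lambda_s : float
        LWM-consistency weight (>= 0) on the neighborhood-mean loss terms.
    C : float
        Fuzzy-entropy weight (> 0); larger C pushes memberships toward 1,
        smaller C sharpens the outlier-suppressing decay.
    beta : float
        Adaptation weight (>= 0); 0 disables the source-model terms entirely.
    eta : float
        Ridge on the source weights (> 0); large eta forces uniform gamma,
        small eta lets gamma concentrate on the closest sources.
    max_iter : int
        Maximum number of full update cycles.
    window : int
        Window length (>= 2) of the stopping criterion.
    eps : float
        Stopping threshold (in (0, 1)) on the relative objective spread.
    membership_lwm_weighted : bool
        If True (default), the LWM distance in the membership update carries
        the ``lambda_s`` factor, consistent with the objective's gradient;
        if False the plain unweighted sum is used.
    divergence : str
        ``"target_scatter"`` (default) or ``"identity"`` — how the model
        discrepancy A_i is weighted (identity is the no-target-scatter
        ablation).
    """

    lam: float = 1.0
    lambda_s: float = 1.0
    C: float = 1.0
    beta: float = 1.0
    eta: float = 1.0
    max_iter: int = 50
    window: int = 5
    eps: float = 1e-4
    membership_lwm_weighted: bool = True
    divergence: str = "target_scatter"

    def __post_init__(self) -> None:
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ParameterError(f"lam must be > 0, got {self.lam}")
        for name in ("lambda_s", "beta"):
            val = getattr(self, name)
            if not (val >= 0 and np.isfinite(val)):
                raise ParameterError(f"{name} must be >= 0, got {val}")
        for name in ("C", "eta"):
            val = getattr(self, name)
            if not (val > 0 and np.isfinite(val)):
                raise ParameterError(f"{name} must be > 0, got {val}")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.window < 2:
            raise ParameterError("window must be >= 2")
        if not (0 < self.eps < 1):
            raise ParameterError("eps must lie in (0, 1)")
        if self.divergence not in DIVERGENCES:
            raise ParameterError(
                f"divergence must be one of {DIVERGENCES}, got {self.divergence!r}"
            )


@dataclass(frozen=True)
class LabelEncoding:
    """Class labels, their one-hot targets and the class prototypes.

    The prototypes ``c_m`` are the one-hot basis vectors of label space, so
    labeled targets and cluster centers live in the same M-dimensional output
    space.
    """

    classes: np.ndarray

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def centers(self) -> np.ndarray:
        return np.eye(self.M)

    def one_hot(self, y: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.classes, y)
        if np.any(idx >= self.M) or np.any(self.classes[idx] != y):
            raise InputError("labels outside the training class set")
        out = np.zeros((len(y), self.M))
        out[np.arange(len(y)), idx] = 1.0
        return out


@dataclass(frozen=True)
class Problem:
    """Assembled training quantities shared by all block updates."""

    K: np.ndarray          # (n, n) Gram matrix
    Kbar: np.ndarray       # (n, n) cross-Gram, row j = kernel(xhat_j, x_:)
    labeled: np.ndarray    # (n,) boolean mask
    Y: np.ndarray          # (n, M) one-hot targets, zero rows when unlabeled
    centers: np.ndarray    # (M, M) class prototypes (rows)
    source_alphas: np.ndarray  # (q, n, M) dual coefficients of the sources
    hp: Hyperparams

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def M(self) -> int:
        return self.Y.shape[1]

    @property
    def q(self) -> int:
        return self.source_alphas.shape[0]


@dataclass
class SolverState:
    """Mutable state carried through the alternating optimization."""

    alpha: np.ndarray
    V: np.ndarray
    gamma: np.ndarray
    obj_history: list = field(default_factory=list)
    partial_history: list = field(default_factory=list)
    iter: int = 0


@dataclass(frozen=True)
class FitResult:
    """Fitted model plus everything needed for out-of-sample evaluation."""

    alpha: np.ndarray
    gamma: np.ndarray
    V: np.ndarray
    kernels: tuple[KernelSpec, ...]
    X: np.ndarray
    Xhat: np.ndarray
    k: int
    tau: float
    encoding: LabelEncoding
    hp: Hyperparams
    labeled_mask: np.ndarray
    converged: bool
    stop_reason: str
    n_iter: int
    obj_history: tuple[float, ...]
    partial_history: tuple[tuple[str, float], ...]

    @property
    def classes(self) -> np.ndarray:
        return self.encoding.classes

    @property
    def centers(self) -> np.ndarray:
        return self.encoding.centers


@dataclass(frozen=True)
class Prediction:
    """Predicted labels, possibilistic memberships and raw decision values."""

    labels: np.ndarray
    memberships: np.ndarray
    decisions: np.ndarray


def make_problem(
    grams: GramPair,
    labeled: np.ndarray,
    Y: np.ndarray,
    centers: np.ndarray,
    source_alphas: Sequence[np.ndarray] | np.ndarray,
    hp: Hyperparams,
) -> Problem:
    """Bundle the training quantities, validating shapes."""
    K = np.asarray(grams.K, dtype=float)
    Kbar = np.asarray(grams.Kbar, dtype=float)
    labeled = np.asarray(labeled, dtype=bool)
    Y = np.asarray(Y, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or Kbar.shape != (n, n):
        raise InputError("K and Kbar must both be n x n")
    if labeled.shape != (n,) or Y.shape[0] != n:
        raise InputError("labeled mask / targets inconsistent with Gram size")
    src = np.asarray(source_alphas, dtype=float)
    if src.size == 0:
        src = np.zeros((0, n, Y.shape[1]))
    if src.ndim != 3 or src.shape[1:] != (n, Y.shape[1]):
        raise InputError(
            "source dual coefficients must share the target reference sample "
            f"and class count: expected (*, {n}, {Y.shape[1]}), got {src.shape}"
        )
    if src.shape[0] == 0 and hp.beta > 0:
        raise ParameterError("q = 0 sources is only permitted with beta = 0")
    return Problem(
        K=K, Kbar=Kbar, labeled=labeled, Y=Y, centers=np.asarray(centers, float),
        source_alphas=src, hp=hp,
    )


def _masked_v2(V: np.ndarray, prob: Problem) -> np.ndarray:
    """Squared memberships with labeled rows zeroed."""
    v2 = np.square(V)
    v2[prob.labeled] = 0.0
    return v2


def adaptation_scores(alpha: np.ndarray, prob: Problem) -> np.ndarray:
    """Per-source model discrepancies A_i.

    With the target-scatter divergence, ``A_i = (1/n) ||K (alpha -
    alpha_i^s)||_F^2`` — the mean squared difference between the target and
    source decision values over the sample.  The identity variant drops the
    Gram weighting.
    """
    out = np.empty(prob.q)
    for i, a_s in enumerate(prob.source_alphas):
        diff = alpha - a_s
        if prob.hp.divergence == "target_scatter":
            out[i] = np.sum(np.square(prob.K @ diff)) / prob.n
        else:
            out[i] = np.sum(np.square(diff)) / prob.n
    return out


def objective(
    alpha: np.ndarray, V: np.ndarray, gamma: np.ndarray, prob: Problem
) -> float:
    """Evaluate the full objective Q(alpha, V, gamma)."""
    hp = prob.hp
    L, U = prob.labeled, ~prob.labeled
    F = prob.K @ alpha
    Fhat = prob.Kbar @ alpha

    total = float(np.sum(np.square(F[L] - prob.Y[L])))
    total += hp.lambda_s * float(np.sum(np.square(Fhat[L] - prob.Y[L])))

    v2 = np.square(V[U])
    if v2.size:
        d2 = cdist(F[U], prob.centers, "sqeuclidean")
        d2h = cdist(Fhat[U], prob.centers, "sqeuclidean")
        total += float(np.sum(v2 * d2)) + hp.lambda_s * float(np.sum(v2 * d2h))
        # v^2 ln v^2 -> 0 as v -> 0 (continuous limit).
        ent = np.where(v2 > 0.0, v2 * np.log(np.maximum(v2, _MEMBERSHIP_FLOOR)), 0.0)
        total += hp.C * float(np.sum(ent - v2))

    total += hp.lam * float(np.einsum("ij,ij->", alpha, prob.K @ alpha))

    if hp.beta > 0 and prob.q > 0:
        A = adaptation_scores(alpha, prob)
        gamma = np.asarray(gamma, dtype=float)
        total += hp.beta * (float(gamma @ A) + hp.eta * float(gamma @ gamma))
    return total


def _solve_sym(H: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``H alpha = B`` with a ridge-jitter fallback for near-singular H."""
    try:
        return solve(H, B, assume_a="sym")
    except LinAlgError:
        jitter = 1e-10 * np.trace(H) / H.shape[0]
        try:
            return solve(H + jitter * np.eye(H.shape[0]), B, assume_a="sym")
        except LinAlgError as exc:  # pragma: no cover - requires pathological K
            raise SingularSystemError(
                "normal-equation matrix is singular; increase lam to "
                "regularize the RKHS norm"
            ) from exc


def normal_equations(
    V: np.ndarray, gamma: np.ndarray, prob: Problem
) -> tuple[np.ndarray, np.ndarray]:
    """The (H, B) of the alpha subproblem's stationarity condition ``H alpha = B``:

        H = K S_L K + lambda_s Kbar^T S_L Kbar
          + K Vhat K + lambda_s Kbar^T Vhat Kbar
          + lam K + (beta/n) (sum_i gamma_i) K K
        B = K S_L Y + lambda_s Kbar^T S_L Y
          + (K + lambda_s Kbar^T) V2 Centers
          + (beta/n) K K sum_i gamma_i alpha_i^s

    where S_L is the labeled-indicator diagonal, V2 the (n, M) matrix of
    squared memberships (zero on labeled rows) and Vhat its row sums.  The
    identity-divergence ablation replaces K K by I in the beta terms.
    """
    hp = prob.hp
    K, Kbar = prob.K, prob.Kbar
    L = prob.labeled
    KL = K[L]          # (l, n); K diag(S_L) K = KL^T KL by symmetry of K
    KbL = Kbar[L]

    v2 = _masked_v2(np.asarray(V, dtype=float), prob)
    vhat = v2.sum(axis=1)

    H = KL.T @ KL + hp.lambda_s * (KbL.T @ KbL)
    H += (K * vhat[None, :]) @ K
    H += hp.lambda_s * (Kbar * vhat[:, None]).T @ Kbar
    H += hp.lam * K

    B = KL.T @ prob.Y[L] + hp.lambda_s * (KbL.T @ prob.Y[L])
    B += (K @ v2 + hp.lambda_s * (Kbar.T @ v2)) @ prob.centers

    if hp.beta > 0 and prob.q > 0:
        gamma = np.asarray(gamma, dtype=float)
        gsum = float(gamma.sum())
        mix = np.einsum("i,inm->nm", gamma, prob.source_alphas)
        scale = hp.beta / prob.n
        if hp.divergence == "target_scatter":
            KK = K @ K
            H += scale * gsum * KK
            B += scale * (KK @ mix)
        else:
            H += scale * gsum * np.eye(prob.n)
            B += scale * mix
    return H, B


def update_alpha(V: np.ndarray, gamma: np.ndarray, prob: Problem) -> np.ndarray:
    """Exact minimizer of Q over alpha with V and gamma fixed.

    Solves the normal equations :func:`normal_equations`; a tiny ridge
    jitter is added only if the plain symmetric solve fails.
    """
    H, B = normal_equations(V, gamma, prob)
    return _solve_sym(H, B)


def update_membership(alpha: np.ndarray, prob: Problem) -> np.ndarray:
    """Closed-form membership update for the unlabeled instances.

    ``v_m(x_j) = exp(-(||f(x_j) - c_m||^2 + w ||f(xhat_j) - c_m||^2) / (2C))``
    with ``w = lambda_s`` when ``membership_lwm_weighted`` else 1.  Values lie
    in (0, 1]; underflow is clamped at 1e-300.  Labeled rows are zero.
    """
    hp = prob.hp
    U = ~prob.labeled
    V = np.zeros((prob.n, prob.M))
    if not np.any(U):
        return V
    F = (prob.K @ alpha)[U]
    Fhat = (prob.Kbar @ alpha)[U]
    d2 = cdist(F, prob.centers, "sqeuclidean")
    d2h = cdist(Fhat, prob.centers, "sqeuclidean")
    w = hp.lambda_s if hp.membership_lwm_weighted else 1.0
    V[U] = np.maximum(np.exp(-(d2 + w * d2h) / (2.0 * hp.C)), _MEMBERSHIP_FLOOR)
    return V


def update_gamma(
    A: np.ndarray, eta: float, gamma0: np.ndarray | None = None
) -> np.ndarray:
    """Minimize ``gamma^T A + eta ||gamma||^2`` over the probability simplex.

    Sweeps the exact pairwise exchange update over all index pairs: for a
    pair (i, j) with mass ``s = gamma_i + gamma_j`` the constrained optimum
    is ``gamma_i = clip(s/2 + (A_j - A_i) / (4 eta), 0, s)`` (the clip covers
    the two boundary cases).  Sweeps repeat until a full sweep moves no
    coordinate by more than 1e-13.  Smaller A_i (source closer to the target)
    always receives the larger weight.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 1 or A.size == 0:
        raise ParameterError("A must be a nonempty 1-D array of source scores")
    if not (eta > 0 and np.isfinite(eta)):
        raise ParameterError(f"eta must be > 0, got {eta}")
    q = A.size
    if q == 1:
        return np.array([1.0])
    if gamma0 is None:
        g = np.full(q, 1.0 / q)
    else:
        g = np.asarray(gamma0, dtype=float).copy()
        if g.shape != (q,) or np.any(g < 0) or abs(g.sum() - 1.0) > 1e-8:
            raise ParameterError("gamma0 must be a simplex vector of length q")
    for _ in range(500):
        moved = 0.0
        for i in range(q - 1):
            for j in range(i + 1, q):
                s = g[i] + g[j]
                gi = 0.5 * s + (A[j] - A[i]) / (4.0 * eta)
                gi = min(max(gi, 0.0), s)
                moved = max(moved, abs(gi - g[i]))
                g[i] = gi
                g[j] = s - gi
        if moved < 1e-13:
            break
    g = np.clip(g, 0.0, 1.0)
    return g / g.sum()


def _normalize_kernels(
    kernels: KernelSpec | Sequence[KernelSpec] | None, d: int
) -> tuple[KernelSpec, ...]:
    if kernels is None:
        kernels = (KernelSpec(),)
    elif isinstance(kernels, KernelSpec):
        kernels = (kernels,)
    else:
        kernels = tuple(kernels)
        if not kernels:
            raise ParameterError("at least one kernel spec is required")
    return tuple(s.resolved(d) for s in kernels)


def _extract_source_alpha(source) -> np.ndarray:
    alpha = getattr(source, "alpha", source)
    return np.asarray(alpha, dtype=float)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    sources: Sequence = (),
    hp: Hyperparams | None = None,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
    k: int = 5,
    tau: float | None = None,
    gamma: np.ndarray | str = "optimal",
) -> FitResult:
    """Train the full model by alternating exact block updates.

    Parameters
    ----------
    X : (n, d) array
        Feature matrix of the target sample.
    y : (n,) integer array
        Class labels; negative entries mark unlabeled instances.  Every class
        must have at least one labeled instance.
    sources : sequence
        Pre-trained source models as objects exposing ``.alpha`` (dual
        coefficients over *this* sample, shape (n, M)) or raw arrays.
    hp, kernels, k, tau
        Hyperparameters, kernel spec(s) (default single Gaussian with
        sigma = 1/d), and graph parameters (tau defaults to the median
        heuristic).
    gamma : "optimal" or simplex array
        ``"optimal"`` optimizes the source weights each cycle; an explicit
        simplex vector keeps them fixed (uniform / distance-based ablations).

    Returns
    -------
    FitResult
    """
    hp = hp or Hyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.shape != (X.shape[0],):
        raise InputError("y must be one integer label per row of X")
    labeled = np.asarray(y >= 0)
    if not np.any(labeled):
        raise InputError("at least one labeled instance is required")
    encoding = LabelEncoding(classes=np.unique(y[labeled]))
    if encoding.M < 2:
        raise InputError("need labeled instances from at least two classes")

    graph = build_graph(X, k=k, tau=tau)
    Xhat = local_weighted_mean(X, graph)
    specs = _normalize_kernels(kernels, X.shape[1])
    grams = gram_pair(X, Xhat, specs)

    n = X.shape[0]
    Y = np.zeros((n, encoding.M))
    Y[labeled] = encoding.one_hot(y[labeled])

    source_alphas = [_extract_source_alpha(s) for s in sources]
    for s in sources:
        ref = getattr(s, "X", None)
        if ref is not None and np.shape(ref) != X.shape:
            raise InputError(
                "source model reference sample does not match the target "
                "sample; project it onto the target first"
            )
        sk = getattr(s, "kernels", None)
        if sk is not None and tuple(k_.resolved(X.shape[1]) for k_ in sk) != specs:
            raise InputError(
                "source model lives in a different kernel space than this fit; "
                "train/project the sources with the same kernel specs"
            )
    prob = make_problem(grams, labeled, Y, encoding.centers, source_alphas, hp)

    optimize_gamma = isinstance(gamma, str)
    if optimize_gamma:
        if gamma != "optimal":
            raise ParameterError(f"unknown gamma mode {gamma!r}")
        g = np.full(prob.q, 1.0 / prob.q) if prob.q else np.zeros(0)
    else:
        g = np.asarray(gamma, dtype=float)
        if g.shape != (prob.q,):
            raise ParameterError("fixed gamma length must equal the source count")
        if prob.q and (np.any(g < 0) or abs(g.sum() - 1.0) > 1e-8):
            raise ParameterError("fixed gamma must lie on the probability simplex")

    state = SolverState(alpha=np.zeros((n, encoding.M)), V=np.zeros((n, encoding.M)), gamma=g)

    # Initialization: memberships at zero, alpha solved from the labeled data
    # (and the beta pull toward the gamma-averaged sources), then memberships
    # from the closed form.
    state.alpha = update_alpha(state.V, state.gamma, prob)
    state.V = update_membership(state.alpha, prob)
    Q = objective(state.alpha, state.V, state.gamma, prob)
    state.obj_history.append(Q)
    state.partial_history.append(("init", Q))
    logger.info("iter 0 (init): Q = %.10g", Q)

    stop_reason = "max_iter"
    varsigma = np.inf
    bad_cycles = 0
    for itr in range(1, hp.max_iter + 1):
        state.iter = itr
        state.alpha = update_alpha(state.V, state.gamma, prob)
        Qa = objective(state.alpha, state.V, state.gamma, prob)
        state.partial_history.append(("alpha", Qa))

        state.V = update_membership(state.alpha, prob)
        Qv = objective(state.alpha, state.V, state.gamma, prob)
        state.partial_history.append(("membership", Qv))

        Qg = Qv
        if optimize_gamma and hp.beta > 0 and prob.q > 1:
            A = adaptation_scores(state.alpha, prob)
            state.gamma = update_gamma(A, hp.eta, state.gamma)
            Qg = objective(state.alpha, state.V, state.gamma, prob)
            state.partial_history.append(("gamma", Qg))

        prev = state.obj_history[-1]
        if Qg > prev + _DESCENT_RTOL * max(1.0, abs(prev)):
            bad_cycles += 1
            if bad_cycles >= 3:
                raise DescentDiagnosticError(
                    "objective increased for 3 consecutive cycles "
                    f"(last {prev:.12g} -> {Qg:.12g}); this indicates an "
                    "implementation or conditioning problem"
                )
        else:
            bad_cycles = 0
        state.obj_history.append(Qg)
        logger.info("iter %d: Q = %.10g", itr, Qg)

        if len(state.obj_history) >= hp.window:
            theta = state.obj_history[-hp.window:]
            mx, mn = max(theta), min(theta)
            varsigma = abs(mx - mn) / max(abs(mx), _MEMBERSHIP_FLOOR)
            if varsigma < hp.eps:
                stop_reason = "window"
                break

    converged = stop_reason == "window"
    logger.info(
        "stopping reason: %s (iterations=%d, varsigma=%.3g, eps=%.3g)",
        stop_reason, state.iter, varsigma, hp.eps,
    )
    if prob.q == 0:
        final_gamma = np.zeros(0)
    else:
        final_gamma = state.gamma
    return FitResult(
        alpha=state.alpha,
        gamma=final_gamma,
        V=state.V,
        kernels=specs,
        X=X,
        Xhat=Xhat,
        k=graph.k,
        tau=graph.tau,
        encoding=encoding,
        hp=hp,
        labeled_mask=labeled,
        converged=converged,
        stop_reason=stop_reason,
        n_iter=state.iter,
        obj_history=tuple(state.obj_history),
        partial_history=tuple(state.partial_history),
    )


def fit_sspca(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparams | None = None,
    kernels: KernelSpec | Sequence[KernelSpec] | None = None,
    k: int = 5,
    tau: float | None = None,
) -> FitResult:
    """The no-adaptation special case: no sources, beta forced to 0.

    This is the degenerate single-domain model the full method reduces to
    when the adaptation weight vanishes.
    """
    hp = hp or Hyperparams()
    return fit(X, y, sources=(), hp=replace(hp, beta=0.0), kernels=kernels, k=k, tau=tau)


def decision_values(result: FitResult, Xnew: np.ndarray) -> np.ndarray:
    """Evaluate ``f(x) = alpha^T k(x)`` on new points (rows)."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim != 2 or Xnew.shape[1] != result.X.shape[1]:
        raise InputError(
            f"expected points with {result.X.shape[1]} features, got shape {Xnew.shape}"
        )
    Kx = sum(gram(Xnew, result.X, s) for s in result.kernels)
    return Kx @ result.alpha


def labels_from_decisions(
    F: np.ndarray, centers: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Nearest class prototype; ties break toward the lowest class index."""
    idx = np.argmin(cdist(F, centers, "sqeuclidean"), axis=1)
    return classes[idx]


def predict(result: FitResult, Xnew: np.ndarray) -> Prediction:
    """Predict labels and possibilistic memberships for new points.

    The predicted class minimizes the distance of the decision value to the
    class prototypes.  Memberships use the same closed form as training, with
    the LWM of each new point taken over its k nearest *training* samples.
    """
    F = decision_values(result, Xnew)
    labels = labels_from_decisions(F, result.centers, result.classes)

    Xnew = np.asarray(Xnew, dtype=float)
    d2 = cdist(Xnew, result.X, "sqeuclidean")
    order = np.argsort(d2, axis=1, kind="stable")[:, : result.k]
    w = np.exp(-result.tau * np.take_along_axis(d2, order, axis=1))
    totals = w.sum(axis=1, keepdims=True)
    totals[totals <= 0.0] = 1.0  # degenerate rows fall back to unweighted mean
    wn = np.where(w.sum(axis=1, keepdims=True) > 0, w / totals, 1.0 / result.k)
    Xhat_new = np.einsum("pk,pkd->pd", wn, result.X[order])
    Khat = sum(gram(Xhat_new, result.X, s) for s in result.kernels)
    Fhat = Khat @ result.alpha

    dc = cdist(F, result.centers, "sqeuclidean")
    dch = cdist(Fhat, result.centers, "sqeuclidean")
    wgt = result.hp.lambda_s if result.hp.membership_lwm_weighted else 1.0
    V = np.maximum(np.exp(-(dc + wgt * dch) / (2.0 * result.hp.C)), _MEMBERSHIP_FLOOR)
    return Prediction(labels=labels, memberships=V, decisions=F)
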