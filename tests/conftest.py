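"""Shared fixtures: random tiny problems and the session-level recovery study."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mapca import (
    Hyperparams,
    KernelSpec,
    build_graph,
    default_multi_kernel,
    fit_task,
    gram_pair,
    local_weighted_mean,
    make_problem,
    make_recovery_task,
    recovery_hyperparams,
)
from mapca.solver import LabelEncoding

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_problem(seed, n=12, M=2, q=2, d=3, hp=None):
    """A random tiny assembled problem plus admissible (V, gamma).

    Labels: the first M instances carry one label per class, a few more are
    labeled at random, the rest are unlabeled.
    """
    rng = np.random.default_rng(seed)
    if hp is None:
        hp = Hyperparams(
            lam=rng.uniform(0.5, 2.0),
            lambda_s=rng.uniform(0.2, 2.0),
            C=rng.uniform(0.5, 2.0),
            beta=rng.uniform(0.2, 2.0),
            eta=rng.uniform(0.2, 2.0),
        )
    X = rng.normal(size=(n, d))
    labeled = np.zeros(n, dtype=bool)
    labeled[:M] = True
    extra = rng.choice(np.arange(M, n), size=max(1, n // 4), replace=False)
    labeled[extra] = True
    y = rng.integers(0, M, size=n)
    y[:M] = np.arange(M)

    graph = build_graph(X, k=3)
    Xhat = local_weighted_mean(X, graph)
    grams = gram_pair(X, Xhat, KernelSpec(sigma=1.0 / d))
    enc = LabelEncoding(classes=np.arange(M))
    Y = np.zeros((n, M))
    Y[labeled] = enc.one_hot(y[labeled])
    src = rng.normal(scale=0.3, size=(q, n, M))
    prob = make_problem(grams, labeled, Y, enc.centers, src, hp)

    V = np.zeros((n, M))
    V[~labeled] = rng.uniform(0.05, 1.0, size=(int((~labeled).sum()), M))
    gamma = rng.dirichlet(np.ones(q)) if q else np.zeros(0)
    return prob, V, gamma


def random_fit_instance(seed, n=30, M=3, q=2, d=3):
    """Random blob data with partial labels and random source coefficients."""
    rng = np.random.default_rng(seed)
    means = rng.normal(scale=3.0, size=(M, d))
    X = np.vstack([
        rng.normal(means[m], 1.0, size=(n // M, d)) for m in range(M)
    ])
    y = np.repeat(np.arange(M), n // M)
    mask = np.zeros(len(y), dtype=bool)
    for m in range(M):
        pool = np.flatnonzero(y == m)
        mask[rng.choice(pool, size=2, replace=False)] = True
    y_partial = np.where(mask, y, -1)
    sources = [rng.normal(scale=0.3, size=(len(y), M)) for _ in range(q)]
    return X, y_partial, sources


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort algorithm)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u * np.arange(1, len(v) + 1) > (css - 1.0))[-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def gamma_qp_oracle(A: np.ndarray, eta: float) -> np.ndarray:
    """Exact solution of min gamma.A + eta ||gamma||^2 on the simplex."""
    return project_simplex(-np.asarray(A, float) / (2.0 * eta))


def objective_by_loops(alpha, V, gamma, prob) -> float:
    """Term-by-term re-implementation of the objective with explicit loops."""
    hp = prob.hp
    n, M = prob.n, prob.M
    F = prob.K @ alpha
    Fh = prob.Kbar @ alpha
    total = 0.0
    for i in range(n):
        if prob.labeled[i]:
            total += float(np.sum((F[i] - prob.Y[i]) ** 2))
            total += hp.lambda_s * float(np.sum((Fh[i] - prob.Y[i]) ** 2))
        else:
            for m in range(M):
                v2 = V[i, m] ** 2
                total += v2 * float(np.sum((F[i] - prob.centers[m]) ** 2))
                total += hp.lambda_s * v2 * float(np.sum((Fh[i] - prob.centers[m]) ** 2))
                ent = v2 * np.log(v2) if v2 > 0 else 0.0
                total += hp.C * (ent - v2)
    total += hp.lam * float(np.trace(alpha.T @ prob.K @ alpha))
    if hp.beta > 0 and prob.q:
        adapt = 0.0
        for i in range(prob.q):
            Fs = prob.K @ prob.source_alphas[i]
            Ai = sum(float(np.sum((F[j] - Fs[j]) ** 2)) for j in range(n)) / n
            adapt += gamma[i] * Ai
        total += hp.beta * (adapt + hp.eta * float(np.sum(np.square(gamma))))
    return total


def membership_grid_oracle(alpha, prob, grid=None) -> np.ndarray:
    """Per-entry 1-D grid search of the membership subproblem."""
    hp = prob.hp
    if grid is None:
        grid = np.linspace(1e-6, 1.0, 20001)
    F = prob.K @ alpha
    Fh = prob.Kbar @ alpha
    w = hp.lambda_s if hp.membership_lwm_weighted else 1.0
    V = np.zeros((prob.n, prob.M))
    g2 = grid ** 2
    ent = g2 * np.log(g2) - g2
    for j in range(prob.n):
        if prob.labeled[j]:
            continue
        for m in range(prob.M):
            dist = float(np.sum((F[j] - prob.centers[m]) ** 2))
            dist += w * float(np.sum((Fh[j] - prob.centers[m]) ** 2))
            V[j, m] = grid[np.argmin(g2 * dist + hp.C * ent)]
    return V


# ---------------------------------------------------------------------------
# the frozen recovery study (shared by acceptance + property tests)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def recovery_study():
    """Fit the two-source recovery benchmark across seeds, once per session."""
    hp = recovery_hyperparams()
    study = {
        "acc_optimal": [], "acc_uniform": [], "gamma_relevant": [],
        "acc_outlier": [], "membership_gap": [],
        "acc_multi": [], "results": [], "outlier_results": [],
    }
    for seed in range(20):
        task = make_recovery_task(seed)
        res, acc = fit_task(task, hp=hp)
        study["results"].append(res)
        study["acc_optimal"].append(acc)
        study["gamma_relevant"].append(res.gamma[list(task.relevance).index(True)])
        _, acc_u = fit_task(task, hp=hp, scheme="uniform")
        study["acc_uniform"].append(acc_u)

        noisy = make_recovery_task(seed, outlier_fraction=0.1)
        res_n, acc_n = fit_task(noisy, hp=hp)
        study["outlier_results"].append((res_n, noisy))
        study["acc_outlier"].append(acc_n)
        dom = noisy.target
        unl = ~dom.labeled_mask
        maxmem = res_n.V.max(axis=1)
        study["membership_gap"].append(
            float(np.median(maxmem[unl & dom.outlier_mask])
                  - np.median(maxmem[unl & ~dom.outlier_mask]))
        )
    multi = default_multi_kernel()
    for seed in range(10):
        task = make_recovery_task(seed, kernels=multi)
        _, acc_m = fit_task(task, hp=hp, kernels=multi)
        study["acc_multi"].append(acc_m)
    return study
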