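"""Block updates against independent oracles (loops, grids, QP projection)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from mapca import (
    Hyperparams,
    ParameterError,
    adaptation_scores,
    normal_equations,
    objective,
    update_alpha,
    update_gamma,
    update_membership,
)
from conftest import (
    gamma_qp_oracle,
    membership_grid_oracle,
    objective_by_loops,
    random_problem,
)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_objective_matches_term_by_term_loop(seed):
    prob, V, gamma = random_problem(seed, n=8, M=2, q=2)
    rng = np.random.default_rng(seed + 100)
    alpha = rng.normal(scale=0.4, size=(prob.n, prob.M))
    assert objective(alpha, V, gamma, prob) == pytest.approx(
        objective_by_loops(alpha, V, gamma, prob), rel=1e-12
    )


def test_objective_zero_model_no_unlabeled_is_label_energy():
    # With beta = 0, alpha = 0 and every instance labeled, only the labeled
    # squared losses survive: l * (1 + lambda_s) for one-hot targets.
    prob, _, _ = random_problem(7, n=10, M=2, q=0,
                                hp=Hyperparams(beta=0.0, lambda_s=0.5))
    prob = prob.__class__(**{**prob.__dict__, "labeled": np.ones(prob.n, bool),
                             "Y": np.tile(np.eye(2), (5, 1))})
    alpha = np.zeros((prob.n, prob.M))
    V = np.zeros((prob.n, prob.M))
    assert objective(alpha, V, np.zeros(0), prob) == pytest.approx(
        prob.n * (1 + 0.5)
    )


def test_objective_entropy_term_at_unit_membership():
    # v = 1 everywhere makes the entropy term contribute -C per (j, m) cell.
    prob, V, gamma = random_problem(11, n=9, M=2, q=2)
    alpha = np.zeros((prob.n, prob.M))
    V1 = np.zeros_like(V)
    V1[~prob.labeled] = 1.0
    n_u = int((~prob.labeled).sum())
    base = objective(alpha, np.zeros_like(V), gamma, prob)
    with_v = objective(alpha, V1, gamma, prob)
    # distances ||0 - c_m||^2 = 1 on both sample and LWM terms
    expected_cluster = n_u * prob.M * (1.0 + prob.hp.lambda_s)
    assert with_v - base == pytest.approx(
        expected_cluster - prob.hp.C * prob.M * n_u, rel=1e-12
    )


# ---------------------------------------------------------------------------
# alpha update
# ---------------------------------------------------------------------------

def test_alpha_residual_and_perturbation_optimality():
    prob, V, gamma = random_problem(21, n=14, M=3, q=2)
    alpha = update_alpha(V, gamma, prob)
    H, B = normal_equations(V, gamma, prob)
    assert np.linalg.norm(H @ alpha - B) / np.linalg.norm(B) < 1e-8
    q0 = objective(alpha, V, gamma, prob)
    rng = np.random.default_rng(99)
    for _ in range(100):
        delta = rng.normal(scale=1e-3, size=alpha.shape)
        assert q0 <= objective(alpha + delta, V, gamma, prob)


def test_huge_rkhs_penalty_shrinks_alpha_to_zero():
    prob, V, gamma = random_problem(22, n=12, M=2, q=2)
    big = Hyperparams(lam=1e8, lambda_s=prob.hp.lambda_s, C=prob.hp.C,
                      beta=prob.hp.beta, eta=prob.hp.eta)
    prob_big = prob.__class__(**{**prob.__dict__, "hp": big})
    alpha = update_alpha(V, gamma, prob_big)
    assert np.linalg.norm(alpha) < 1e-6


def test_alpha_matches_independent_numerical_minimizer():
    """BFGS on the loop objective (finite-difference-free via loop gradient)."""
    prob, V, gamma = random_problem(23, n=10, M=2, q=2)
    alpha_star = update_alpha(V, gamma, prob)

    def grad_by_loops(alpha):
        hp = prob.hp
        F = prob.K @ alpha
        Fh = prob.Kbar @ alpha
        g = np.zeros_like(alpha)
        for i in range(prob.n):
            if prob.labeled[i]:
                g += 2.0 * np.outer(prob.K[:, i], F[i] - prob.Y[i])
                g += 2.0 * hp.lambda_s * np.outer(prob.Kbar[i], Fh[i] - prob.Y[i])
            else:
                for m in range(prob.M):
                    v2 = V[i, m] ** 2
                    g += 2.0 * v2 * np.outer(prob.K[:, i], F[i] - prob.centers[m])
                    g += 2.0 * hp.lambda_s * v2 * np.outer(
                        prob.Kbar[i], Fh[i] - prob.centers[m])
        g += 2.0 * hp.lam * prob.K @ alpha
        for s in range(prob.q):
            Fs = prob.K @ prob.source_alphas[s]
            for j in range(prob.n):
                g += (2.0 * hp.beta * gamma[s] / prob.n) * np.outer(
                    prob.K[:, j], F[j] - Fs[j])
        return g

    shape = alpha_star.shape
    res = minimize(
        lambda a: objective_by_loops(a.reshape(shape), V, gamma, prob),
        np.zeros(alpha_star.size),
        jac=lambda a: grad_by_loops(a.reshape(shape)).ravel(),
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 5000},
    )
    np.testing.assert_allclose(res.x.reshape(shape), alpha_star, atol=1e-5)


# ---------------------------------------------------------------------------
# membership update
# ---------------------------------------------------------------------------

def test_membership_matches_grid_search_oracle():
    prob, V, gamma = random_problem(31, n=10, M=2, q=2)
    alpha = update_alpha(V, gamma, prob)
    Vnew = update_membership(alpha, prob)
    Vgrid = membership_grid_oracle(alpha, prob)
    unl = ~prob.labeled
    assert np.max(np.abs(Vnew[unl] - Vgrid[unl])) < 1e-4


def test_membership_limits_and_exact_hit():
    prob, V, gamma = random_problem(32, n=10, M=2, q=2)
    alpha = update_alpha(V, gamma, prob)
    # C -> infinity: memberships -> 1; C -> 0+: -> 0 at nonzero distance
    for C, target in ((1e12, 1.0), (1e-12, 0.0)):
        hp = Hyperparams(lam=prob.hp.lam, lambda_s=prob.hp.lambda_s, C=C,
                         beta=prob.hp.beta, eta=prob.hp.eta)
        p = prob.__class__(**{**prob.__dict__, "hp": hp})
        Vlim = update_membership(alpha, p)[~prob.labeled]
        np.testing.assert_allclose(Vlim, target, atol=1e-6)
    # zero distance on both sample and LWM terms gives v = 1 exactly
    p0 = prob.__class__(**{**prob.__dict__,
                           "K": np.zeros_like(prob.K),
                           "Kbar": np.zeros_like(prob.Kbar)})
    V0 = update_membership(np.zeros_like(alpha), p0)
    # f = 0 everywhere; distance to center c_m is 1, so v = exp(-(1+ls)/2C)
    hp = prob.hp
    expected = np.exp(-(1.0 + hp.lambda_s) / (2.0 * hp.C))
    np.testing.assert_allclose(V0[~prob.labeled], expected, rtol=1e-12)


def test_membership_decreases_with_decision_distance():
    prob, V, gamma = random_problem(33, n=12, M=3, q=2)
    alpha = update_alpha(V, gamma, prob)
    Vnew = update_membership(alpha, prob)
    F = (prob.K @ alpha)[~prob.labeled]
    Fh = (prob.Kbar @ alpha)[~prob.labeled]
    w = prob.hp.lambda_s
    from scipy.spatial.distance import cdist
    d = cdist(F, prob.centers, "sqeuclidean") + w * cdist(Fh, prob.centers, "sqeuclidean")
    # within each row, larger combined distance gives strictly lower v
    for vrow, drow in zip(Vnew[~prob.labeled], d):
        order = np.argsort(drow)
        assert np.all(np.diff(vrow[order]) <= 0)


# ---------------------------------------------------------------------------
# adaptation scores and gamma update
# ---------------------------------------------------------------------------

def test_adaptation_scores_match_pointwise_loop_and_quadratic_scaling():
    prob, V, gamma = random_problem(41, n=10, M=2, q=3)
    alpha = update_alpha(V, gamma, prob)
    A = adaptation_scores(alpha, prob)
    F = prob.K @ alpha
    for i in range(prob.q):
        Fs = prob.K @ prob.source_alphas[i]
        expected = sum(float(np.sum((F[j] - Fs[j]) ** 2)) for j in range(prob.n)) / prob.n
        assert A[i] == pytest.approx(expected, rel=1e-12)
    # identical model -> zero; scaling the difference scales A quadratically
    p_same = prob.__class__(**{**prob.__dict__,
                               "source_alphas": np.stack([alpha] * 2)})
    np.testing.assert_allclose(adaptation_scores(alpha, p_same), 0.0, atol=1e-20)
    scaled = prob.__class__(**{**prob.__dict__,
                               "source_alphas": np.stack(
                                   [alpha + 2.0 * (prob.source_alphas[0] - alpha)])})
    A1 = adaptation_scores(alpha, prob)[0]
    assert adaptation_scores(alpha, scaled)[0] == pytest.approx(4.0 * A1, rel=1e-12)


def test_gamma_trivial_cases():
    np.testing.assert_array_equal(update_gamma(np.array([3.7]), eta=0.5), [1.0])
    np.testing.assert_allclose(
        update_gamma(np.full(4, 2.2), eta=0.3), np.full(4, 0.25), atol=1e-12
    )
    with pytest.raises(ParameterError):
        update_gamma(np.zeros(0), eta=1.0)
    with pytest.raises(ParameterError):
        update_gamma(np.array([1.0, 2.0]), eta=0.0)


def test_gamma_matches_simplex_projection_qp_oracle():
    rng = np.random.default_rng(6)
    for _ in range(20):
        q = rng.integers(2, 6)
        A = rng.uniform(0.0, 3.0, size=q)
        eta = rng.uniform(0.05, 2.0)
        got = update_gamma(A, eta)
        np.testing.assert_allclose(got, gamma_qp_oracle(A, eta), atol=1e-8)


@given(st.integers(0, 10_000))
def test_gamma_simplex_and_ordering_invariants(seed):
    rng = np.random.default_rng(seed)
    q = int(rng.integers(2, 7))
    A = rng.uniform(0.0, 10.0, size=q)
    eta = float(rng.uniform(0.01, 10.0))
    g = update_gamma(A, eta)
    assert g.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(g >= 0.0) and np.all(g <= 1.0)
    order = np.argsort(A, kind="stable")
    assert np.all(np.diff(g[order]) <= 1e-12)  # smaller A -> larger weight
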