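"""End-to-end solver behavior: descent, degeneracies, stopping, prediction."""

import logging

import numpy as np
import pytest

from mapca import (
    Hyperparams,
    InputError,
    KernelSpec,
    decision_values,
    fit,
    fit_sspca,
    gram,
    predict,
)
from mapca.synthdata import DomainConfig, make_domain
from conftest import random_fit_instance


def descent_ok(history, rtol=1e-9):
    vals = [v for _, v in history]
    return all(
        nxt <= prev + rtol * max(1.0, abs(prev))
        for prev, nxt in zip(vals, vals[1:])
    )


@pytest.mark.parametrize("seed", range(5))
def test_partial_updates_never_increase_objective(seed):
    X, y, sources = random_fit_instance(seed)
    result = fit(X, y, sources=sources, hp=Hyperparams(max_iter=20), k=4)
    assert descent_ok(result.partial_history)
    full = list(result.obj_history)
    assert all(b <= a + 1e-9 * max(1.0, abs(a)) for a, b in zip(full, full[1:]))


def test_beta_zero_is_bit_identical_to_sspca_path():
    X, y, sources = random_fit_instance(42)
    hp = Hyperparams(beta=0.0)
    with_sources = fit(X, y, sources=sources, hp=hp, k=4)
    sspca = fit_sspca(X, y, hp=Hyperparams(), k=4)  # beta forced to 0 inside
    assert np.max(np.abs(with_sources.alpha - sspca.alpha)) < 1e-10
    assert np.max(np.abs(with_sources.V - sspca.V)) < 1e-10
    np.testing.assert_allclose(
        with_sources.obj_history, sspca.obj_history, rtol=0, atol=1e-10
    )


def test_single_source_forces_unit_gamma():
    X, y, sources = random_fit_instance(7, q=1)
    result = fit(X, y, sources=sources, hp=Hyperparams(max_iter=10), k=4)
    np.testing.assert_array_equal(result.gamma, [1.0])


def test_no_sources_requires_beta_zero():
    X, y, _ = random_fit_instance(8, q=0)
    with pytest.raises(Exception, match="beta"):
        fit(X, y, sources=(), hp=Hyperparams(beta=1.0), k=4)


def test_fit_is_deterministic():
    X, y, sources = random_fit_instance(3)
    r1 = fit(X, y, sources=sources, k=4)
    r2 = fit(X, y, sources=sources, k=4)
    assert r1.alpha.tobytes() == r2.alpha.tobytes()
    assert r1.obj_history == r2.obj_history


def test_stopping_reason_is_logged_and_window_triggers(caplog):
    X, y, sources = random_fit_instance(11)
    with caplog.at_level(logging.INFO, logger="mapca.solver"):
        result = fit(X, y, sources=sources, k=4)
    assert result.stop_reason == "window"
    assert result.converged and result.n_iter < result.hp.max_iter
    assert any("stopping reason: window" in rec.getMessage()
               for rec in caplog.records)


def test_max_iter_stop_reason_when_budget_is_tiny():
    X, y, sources = random_fit_instance(12)
    result = fit(X, y, sources=sources, hp=Hyperparams(max_iter=2), k=4)
    assert result.stop_reason == "max_iter" and not result.converged


def _separable_domain(seed=5):
    return make_domain(DomainConfig(
        M=3, d=4, n_per_class=20, separation=6.0, labeled_fraction=0.3, seed=seed,
    ))


def test_labeled_points_classified_as_their_own_label_when_separable():
    dom = _separable_domain()
    result = fit_sspca(dom.X, dom.y_partial, hp=Hyperparams(lam=1e-3))
    lab = dom.labeled_mask
    pred = predict(result, dom.X[lab])
    np.testing.assert_array_equal(pred.labels, dom.y[lab])


def test_predict_matches_pointwise_loop_scorer():
    dom = _separable_domain(6)
    result = fit_sspca(dom.X, dom.y_partial)
    rng = np.random.default_rng(0)
    Xnew = rng.normal(scale=3.0, size=(200, 4)) + 1.5
    pred = predict(result, Xnew)

    spec = result.kernels[0]
    for i in range(0, 200, 7):  # spot-check a spread of points
        x = Xnew[i]
        kx = gram(x[None, :], result.X, spec)[0]
        f = result.alpha.T @ kx
        dists = [np.sum((f - c) ** 2) for c in result.centers]
        assert pred.labels[i] == result.classes[int(np.argmin(dists))]
        # LWM over the k nearest training points
        d2 = np.sum((result.X - x) ** 2, axis=1)
        nbr = np.argsort(d2, kind="stable")[: result.k]
        w = np.exp(-result.tau * d2[nbr])
        xhat = (w[:, None] * result.X[nbr]).sum(0) / w.sum()
        fh = result.alpha.T @ gram(xhat[None, :], result.X, spec)[0]
        dh = [np.sum((fh - c) ** 2) for c in result.centers]
        v = np.exp(-(np.array(dists) + result.hp.lambda_s * np.array(dh)) / (2 * result.hp.C))
        np.testing.assert_allclose(pred.memberships[i], v, rtol=1e-10)


def test_membership_argmax_agrees_with_decision_rule_on_separable_data():
    dom = _separable_domain(7)
    result = fit_sspca(dom.X, dom.y_partial)
    pred = predict(result, dom.X[~dom.labeled_mask])
    assert np.all(pred.memberships > 0.0) and np.all(pred.memberships <= 1.0)
    by_membership = result.classes[np.argmax(pred.memberships, axis=1)]
    np.testing.assert_array_equal(by_membership, pred.labels)


def test_dimension_mismatch_raises_input_error():
    X, y, sources = random_fit_instance(13)
    result = fit(X, y, sources=sources, k=4)
    with pytest.raises(InputError):
        decision_values(result, np.zeros((3, X.shape[1] + 1)))


def test_identity_divergence_path_also_descends():
    X, y, sources = random_fit_instance(14)
    hp = Hyperparams(divergence="identity", max_iter=15)
    result = fit(X, y, sources=sources, hp=hp, k=4)
    assert descent_ok(result.partial_history)


def test_fixed_gamma_must_be_simplex():
    X, y, sources = random_fit_instance(15)
    with pytest.raises(Exception, match="simplex"):
        fit(X, y, sources=sources, gamma=np.array([0.9, 0.9]), k=4)
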