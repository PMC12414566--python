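"""Estimation: EM correctness, multistart determinism, oracle agreement."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from growthmix.estimation import StartProtocol, _Engine, fit, multistart_replicated
from growthmix.models import (
    Family,
    GrowthParameters,
    LongitudinalDataset,
    ModelSpec,
    ResidualStructure,
    marginal_loglik,
)
from growthmix.selection import permute_classes
from growthmix.simulate import generate_from_model

TIMES9 = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)
FAST = StartProtocol(n_starts=6, n_final_stage=2, polish=False, max_doublings=0)


def test_single_class_gbtm_equals_polynomial_ols(gbtm2_dataset):
    data, _ = gbtm2_dataset
    spec = ModelSpec(Family.GBTM, 1, (2,), (), ResidualStructure.FIXED, TIMES9)
    fitted = fit(spec, data, StartProtocol(n_starts=1, polish=False), seed=0)
    X = np.vander(np.asarray(TIMES9), 3, increasing=True)
    Xs = np.tile(X, (data.n_subjects, 1))
    beta_ols, *_ = np.linalg.lstsq(Xs, data.y.ravel(), rcond=None)
    resid = data.y.ravel() - Xs @ beta_ols
    sigma2_ml = resid @ resid / resid.size
    assert np.allclose(fitted.params.growth_coefficients[0], beta_ols, atol=1e-6)
    assert fitted.params.residual_variances == pytest.approx(sigma2_ml, abs=1e-6)


def test_em_loglik_sequence_is_monotone(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    factor = 24.0
    spec_s = dataclasses.replace(
        gbtm2_spec, visit_times=tuple(t / factor for t in TIMES9)
    )
    eng = _Engine(spec_s, data.with_time_factor(factor))
    params = eng.initial_params(np.random.default_rng(0))
    lls = []
    for _ in range(50):
        w, ll, cache = eng.estep(params)
        lls.append(ll)
        params = eng.m_step(w, params, cache)
    diffs = np.diff(lls)
    assert np.all(diffs >= -1e-8 * (np.abs(lls[:-1]) + 1))


def test_fit_is_deterministic_given_seed(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    a = fit(gbtm2_spec, data, FAST, seed=5)
    b = fit(gbtm2_spec, data, FAST, seed=5)
    assert a.loglik == b.loglik
    assert np.array_equal(a.posteriors, b.posteriors)
    assert np.array_equal(a.modal_assignment, b.modal_assignment)


def test_parameter_recovery_two_class_gbtm(gbtm2_spec, gbtm2_params, gbtm2_dataset):
    data, labels = gbtm2_dataset
    fitted = fit(gbtm2_spec, data, FAST, seed=1)
    # align by baseline level
    order = np.argsort([b[0] for b in fitted.params.growth_coefficients])
    fitted = permute_classes(fitted, order)
    assert np.allclose(
        fitted.params.class_proportions, gbtm2_params.class_proportions, atol=0.06
    )
    for k in range(2):
        assert np.allclose(
            fitted.params.growth_coefficients[k],
            gbtm2_params.growth_coefficients[k],
            atol=3 * np.asarray(fitted.se_growth_coefficients[k]) + 1e-6,
        )


def test_label_permutation_preserves_loglik(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    fitted = fit(gbtm2_spec, data, FAST, seed=2)
    permuted = permute_classes(fitted, [1, 0])
    assert marginal_loglik(permuted.spec, permuted.params, data) == pytest.approx(
        fitted.loglik, abs=1e-6
    )


def test_gcm_agrees_with_generic_optimizer_oracle():
    # complete balanced data, one class with random intercept + slope
    times = (0.0, 6.0, 12.0, 24.0)
    spec = ModelSpec(
        Family.GCM, 1, (1,), ("intercept", "linear_slope"),
        ResidualStructure.FIXED, times,
    )
    params = GrowthParameters(
        [1.0], (np.array([10.0, -0.3]),),
        np.array([[4.0, -0.05], [-0.05, 0.01]]), 2.0,
    )
    sim = generate_from_model(spec, params, 150, seed=3)
    data = sim.outcomes["outcome"]
    fitted = fit(spec, data, StartProtocol(n_starts=1, polish=True), seed=0)

    t = np.asarray(times)
    Z = np.column_stack([np.ones_like(t), t])
    X = np.vander(t, 2, increasing=True)

    def neg_ll(x):
        beta = x[:2]
        L = np.array([[np.exp(x[2]), 0.0], [x[3], np.exp(x[4])]])
        psi = L @ L.T
        s2 = np.exp(x[5])
        V = Z @ psi @ Z.T + s2 * np.eye(4)
        try:
            return -multivariate_normal.logpdf(data.y, X @ beta, V).sum()
        except np.linalg.LinAlgError:
            return 1e12

    best = np.inf
    for s in range(4):
        rng = np.random.default_rng(s)
        x0 = np.concatenate([[9 + rng.normal(), -0.3 + 0.1 * rng.normal()],
                             rng.normal(scale=0.5, size=4)])
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        best = min(best, res.fun)
    assert fitted.loglik == pytest.approx(-best, abs=1e-4)


def test_multistart_replicated_reports_replication(gbtm2_dataset):
    data, _ = gbtm2_dataset
    spec = ModelSpec(Family.GBTM, 1, (2,), (), ResidualStructure.FIXED, TIMES9)
    fitted = multistart_replicated(spec, data, FAST, seed=0)
    report = fitted.convergence_report
    assert report["replicated_between_runs"] is True
    assert report["n_doublings_used"] == 0


def test_multistart_replicated_deterministic(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    a = multistart_replicated(gbtm2_spec, data, FAST, seed=9)
    b = multistart_replicated(gbtm2_spec, data, FAST, seed=9)
    assert a.loglik == b.loglik
    assert np.array_equal(a.posteriors, b.posteriors)


def test_empty_dataset_rejected(gbtm2_spec):
    empty = LongitudinalDataset(
        subject_ids=np.arange(1), visit_times=TIMES9, y=np.full((1, 9), 1.0)
    ).subset(np.array([], dtype=int))
    with pytest.raises(ValueError):
        fit(gbtm2_spec, empty, FAST, 0)
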