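"""Core model layer: parameter counting, FIML likelihood, posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from growthmix.models import (
    Family,
    GrowthParameters,
    LongitudinalDataset,
    ModelSpec,
    ResidualStructure,
    class_mean_trajectory,
    class_posteriors,
    count_parameters,
    marginal_loglik,
)

TIMES9 = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


def spec_gmm_cv():
    return ModelSpec(
        Family.GMM_CLASS_VARIANT, 2, (3, 3), ("intercept", "linear_slope"),
        ResidualStructure.FREE_BOTH, TIMES9,
    )


@pytest.mark.parametrize(
    "spec, expected",
    [
        # 2-class cubic, class-variant intercept+slope, residuals free both ways
        (spec_gmm_cv(), 33),
        # 3-class cubic/cubic/linear, shared RE covariance, residuals per class
        (
            ModelSpec(
                Family.GMM_CLASS_INVARIANT, 3, (3, 3, 1),
                ("intercept", "linear_slope"),
                ResidualStructure.FREE_OVER_CLASSES, TIMES9,
            ),
            18,
        ),
        # 2-class quadratic GBTM with one shared residual variance
        (
            ModelSpec(
                Family.GBTM, 2, (2, 2), (), ResidualStructure.FIXED,
                (0.0, 12.0, 24.0),
            ),
            8,
        ),
        # single-class quadratic growth curve with intercept+slope REs
        (
            ModelSpec(
                Family.GCM, 1, (2,), ("intercept", "linear_slope"),
                ResidualStructure.FIXED, (0.0, 12.0, 24.0),
            ),
            7,
        ),
    ],
)
def test_count_parameters(spec, expected):
    assert count_parameters(spec) == expected


@pytest.mark.parametrize(
    "kwargs",
    [
        # cubic needs at least four visits
        dict(family=Family.GBTM, n_classes=1, poly_order_per_class=(3,),
             visit_times=(0.0, 12.0, 24.0)),
        # GCM is single class
        dict(family=Family.GCM, n_classes=2, poly_order_per_class=(2, 2),
             visit_times=(0.0, 12.0, 24.0)),
        # GBTM admits no random effects
        dict(family=Family.GBTM, n_classes=2, poly_order_per_class=(2, 2),
             random_effect_terms=("intercept",), visit_times=(0.0, 12.0, 24.0)),
        # LCGA requires a relaxed residual structure
        dict(family=Family.LCGA, n_classes=2, poly_order_per_class=(2, 2),
             residual_structure=ResidualStructure.FIXED,
             visit_times=(0.0, 12.0, 24.0)),
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelSpec(**kwargs)


def test_class_mean_trajectory_polynomial_evaluation():
    params = GrowthParameters(
        [0.5, 0.3, 0.2],
        (np.array([5.0, 0.0, 0.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 2.0, 3.0])),
        None,
        1.0,
    )
    assert np.allclose(class_mean_trajectory(params, 0, [0, 7, 24]), 5.0)
    assert np.allclose(class_mean_trajectory(params, 1, [0, 12, 24]), [0, 12, 24])
    assert class_mean_trajectory(params, 2, [2.0])[0] == pytest.approx(17.0)


def _random_instance(rng, n=4, T=3, missing=True):
    spec = ModelSpec(
        Family.GMM_CLASS_VARIANT, 2, (1, 2), ("intercept", "linear_slope"),
        ResidualStructure.FREE_BOTH, (0.0, 1.0, 3.0),
    )
    A1, A2 = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
    params = GrowthParameters(
        rng.dirichlet([2, 2]),
        (rng.normal(size=2), rng.normal(size=3)),
        (A1 @ A1.T + 0.1 * np.eye(2), A2 @ A2.T + 0.1 * np.eye(2)),
        rng.uniform(0.5, 2.0, size=(2, T)),
    )
    y = rng.normal(size=(n, T))
    if missing:
        y[0, 1] = np.nan
        y[-1, 0] = np.nan
    data = LongitudinalDataset(np.arange(n), (0.0, 1.0, 3.0), y)
    return spec, params, data


def _dense_mixture_loglik(spec, params, data):
    """Independent oracle: dense multivariate-normal mixture density."""
    t = np.asarray(spec.visit_times)
    Z = np.column_stack([np.ones_like(t), t])
    covs = params.re_covariances(spec)
    theta = params.residual_table(spec)
    total = 0.0
    for i in range(data.n_subjects):
        obs = ~np.isnan(data.y[i])
        li = 0.0
        for k in range(spec.n_classes):
            beta = params.growth_coefficients[k]
            X = np.vander(t, beta.size, increasing=True)
            mu = (X @ beta)[obs]
            V = (Z @ covs[k] @ Z.T + np.diag(theta[k]))[np.ix_(obs, obs)]
            li += params.class_proportions[k] * multivariate_normal.pdf(
                data.y[i][obs], mu, V
            )
        total += np.log(li)
    return total


def test_marginal_loglik_matches_dense_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        spec, params, data = _random_instance(rng)
        assert marginal_loglik(spec, params, data) == pytest.approx(
            _dense_mixture_loglik(spec, params, data), abs=1e-8
        )


def test_single_observation_normal_density():
    spec = ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED, (0.0, 1.0))
    sigma2 = 2.5
    params = GrowthParameters([1.0], (np.array([4.0, 0.0]),), None, sigma2)
    y = np.array([[4.0, np.nan]])  # one visit observed, value at the mean
    data = LongitudinalDataset([0], (0.0, 1.0), y)
    assert marginal_loglik(spec, params, data) == pytest.approx(
        -0.5 * np.log(2 * np.pi * sigma2)
    )


def test_mixture_collapse_with_identical_components():
    rng = np.random.default_rng(3)
    spec, params, data = _random_instance(rng)
    # both classes share component 0's parameters: mixture reduces to K=1
    params2 = GrowthParameters(
        np.array([0.3, 0.7]),
        (params.growth_coefficients[0], params.growth_coefficients[0]),
        (params.re_covariance[0], params.re_covariance[0]),
        np.vstack([params.residual_table(spec)[0]] * 2),
    )
    spec1 = ModelSpec(
        Family.GMM_CLASS_INVARIANT, 1, (1,), ("intercept", "linear_slope"),
        ResidualStructure.FREE_OVER_TIME, spec.visit_times,
    )
    params1 = GrowthParameters(
        [1.0], (params.growth_coefficients[0],), params.re_covariance[0],
        params.residual_table(spec)[0],
    )
    assert marginal_loglik(spec, params2, data) == pytest.approx(
        marginal_loglik(spec1, params1, data), abs=1e-10
    )


def test_fiml_reduces_to_complete_data_likelihood():
    rng = np.random.default_rng(7)
    spec, params, data = _random_instance(rng, missing=False)
    ll_complete = marginal_loglik(spec, params, data)
    # re-declaring the same observations (zero visits marked missing)
    data2 = LongitudinalDataset(
        data.subject_ids, data.visit_times, data.y.copy()
    )
    assert marginal_loglik(spec, params, data2) == pytest.approx(ll_complete)


def test_posteriors_match_bayes_oracle_and_sum_to_one():
    rng = np.random.default_rng(5)
    spec, params, data = _random_instance(rng)
    post = class_posteriors(spec, params, data)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)
    # brute-force Bayes from the dense densities
    t = np.asarray(spec.visit_times)
    Z = np.column_stack([np.ones_like(t), t])
    covs = params.re_covariances(spec)
    theta = params.residual_table(spec)
    for i in range(data.n_subjects):
        obs = ~np.isnan(data.y[i])
        dens = []
        for k in range(2):
            beta = params.growth_coefficients[k]
            X = np.vander(t, beta.size, increasing=True)
            V = (Z @ covs[k] @ Z.T + np.diag(theta[k]))[np.ix_(obs, obs)]
            dens.append(
                params.class_proportions[k]
                * multivariate_normal.pdf(data.y[i][obs], (X @ beta)[obs], V)
            )
        dens = np.array(dens)
        assert np.allclose(post[i], dens / dens.sum(), atol=1e-10)


def test_degenerate_prior_gives_degenerate_posterior():
    rng = np.random.default_rng(9)
    spec, params, data = _random_instance(rng)
    params.class_proportions = np.array([1.0, 0.0])
    post = class_posteriors(spec, params, data)
    assert np.allclose(post[:, 0], 1.0)


def test_symmetric_subject_gets_half_half_posterior():
    spec = ModelSpec(Family.GBTM, 2, (1, 1), (), ResidualStructure.FIXED, (0.0, 1.0))
    params = GrowthParameters(
        [0.5, 0.5], (np.array([-1.0, 0.0]), np.array([1.0, 0.0])), None, 1.0
    )
    data = LongitudinalDataset([0], (0.0, 1.0), np.array([[0.0, 0.0]]))
    assert np.allclose(class_posteriors(spec, params, data)[0], [0.5, 0.5])


def test_likelihood_invariant_under_label_permutation():
    rng = np.random.default_rng(13)
    spec, params, data = _random_instance(rng)
    swapped_spec = ModelSpec(
        spec.family, 2, spec.poly_order_per_class[::-1], spec.random_effect_terms,
        spec.residual_structure, spec.visit_times,
    )
    swapped = GrowthParameters(
        params.class_proportions[::-1].copy(),
        params.growth_coefficients[::-1],
        params.re_covariance[::-1],
        np.asarray(params.residual_variances)[::-1].copy(),
    )
    assert marginal_loglik(spec, params, data) == pytest.approx(
        marginal_loglik(swapped_spec, swapped, data), abs=1e-10
    )
    post = class_posteriors(spec, params, data)
    post_sw = class_posteriors(swapped_spec, swapped, data)
    assert np.allclose(post, post_sw[:, ::-1], atol=1e-10)


@settings(derandomize=True, deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_posterior_rows_always_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    spec, params, data = _random_instance(rng)
    post = class_posteriors(spec, params, data)
    assert np.all(np.isfinite(post))
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)


def test_dataset_requires_an_observed_visit():
    y = np.array([[1.0, 2.0], [np.nan, np.nan]])
    with pytest.raises(ValueError, match="no observed visits"):
        LongitudinalDataset([0, 1], (0.0, 1.0), y)


def test_dataset_enforces_value_range():
    y = np.array([[150.0, 20.0]])
    with pytest.raises(ValueError, match="outside declared range"):
        LongitudinalDataset([0], (0.0, 1.0), y, value_range=(0.0, 100.0))
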