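"""Synthetic cohort generator: exactness, calibration, determinism."""

import numpy as np
import pytest

from growthmix.models import (
    Family,
    GrowthParameters,
    ModelSpec,
    ResidualStructure,
)
from growthmix.simulate import (
    calibrate_coupling,
    curve_from_anchors,
    default_config,
    generate_cohort,
    generate_from_model,
    implied_rr,
)

TIMES9 = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


# ---------------------------------------------------------------------------
# curve_from_anchors
# ---------------------------------------------------------------------------


def test_exact_interpolation_with_matching_anchor_count():
    coef = curve_from_anchors([(0, 40.0), (12, 70.0), (24, 76.4)], 2)
    t = np.array([0.0, 12.0, 24.0])
    fitted = np.vander(t, 3, increasing=True) @ coef
    assert np.allclose(fitted, [40.0, 70.0, 76.4])


def test_constant_anchors_give_zero_higher_order_terms():
    coef = curve_from_anchors([(0, 5.0), (6, 5.0), (12, 5.0), (24, 5.0)], 2)
    assert coef[0] == pytest.approx(5.0)
    assert np.allclose(coef[1:], 0.0, atol=1e-12)


def test_least_squares_matches_normal_equations():
    rng = np.random.default_rng(0)
    t = np.array([0.0, 3.0, 9.0, 24.0])
    v = 2.0 + 0.5 * t + rng.normal(size=4)
    coef = curve_from_anchors(list(zip(t, v)), 1)
    X = np.vander(t, 2, increasing=True)
    oracle = np.linalg.solve(X.T @ X, X.T @ v)
    assert np.allclose(coef, oracle)


def test_underdetermined_anchors_error():
    with pytest.raises(ValueError):
        curve_from_anchors([(0, 1.0), (24, 2.0)], 2)


# ---------------------------------------------------------------------------
# generate_from_model
# ---------------------------------------------------------------------------


def test_noiseless_limit_puts_subjects_on_class_means():
    spec = ModelSpec(
        Family.GMM_CLASS_INVARIANT, 2, (1, 1), ("intercept",),
        ResidualStructure.FIXED, (0.0, 12.0, 24.0),
    )
    params = GrowthParameters(
        [0.5, 0.5], (np.array([1.0, 0.0]), np.array([5.0, 0.1])),
        np.zeros((1, 1)), 1e-12,
    )
    sim = generate_from_model(spec, params, 50, seed=0)
    y = sim.outcomes["outcome"].y
    labels = sim.true_classes["outcome"]
    t = np.array([0.0, 12.0, 24.0])
    for k, beta in enumerate(params.growth_coefficients):
        mu = np.vander(t, 2, increasing=True) @ beta
        assert np.allclose(y[labels == k], mu, atol=1e-4)


def test_class_frequencies_follow_proportions():
    spec = ModelSpec(Family.GBTM, 2, (1, 1), (), ResidualStructure.FIXED, (0.0, 1.0))
    params = GrowthParameters(
        [0.3, 0.7], (np.zeros(2), np.ones(2)), None, 1.0
    )
    sim = generate_from_model(spec, params, 10_000, seed=1)
    freq = np.mean(sim.true_classes["outcome"] == 0)
    se = np.sqrt(0.3 * 0.7 / 10_000)
    assert abs(freq - 0.3) < 4 * se


def test_single_class_covariance_matches_model():
    spec = ModelSpec(
        Family.GMM_CLASS_INVARIANT, 1, (1,), ("intercept", "linear_slope"),
        ResidualStructure.FIXED, (0.0, 6.0, 12.0, 24.0),
    )
    psi = np.array([[4.0, -0.05], [-0.05, 0.02]])
    params = GrowthParameters([1.0], (np.array([10.0, -0.2]),), psi, 2.0)
    sim = generate_from_model(spec, params, 8000, seed=2)
    y = sim.outcomes["outcome"].y
    t = np.array([0.0, 6.0, 12.0, 24.0])
    Z = np.column_stack([np.ones(4), t])
    target = Z @ psi @ Z.T + 2.0 * np.eye(4)
    emp = np.cov(y.T)
    assert np.allclose(emp, target, rtol=0.12, atol=0.35)


def test_same_seed_identical_different_seed_distinct():
    spec = ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED, (0.0, 1.0))
    params = GrowthParameters([1.0], (np.array([1.0, 0.0]),), None, 1.0)
    a = generate_from_model(spec, params, 20, seed=3).outcomes["outcome"].y
    b = generate_from_model(spec, params, 20, seed=3).outcomes["outcome"].y
    c = generate_from_model(spec, params, 20, seed=4).outcomes["outcome"].y
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def test_default_cohort_missingness_near_printed_rates():
    cohort = generate_cohort(default_config(n_subjects=689, seed=0))
    saps_missing = 1 - cohort.outcomes["saps"].mask.mean()
    sans_missing = 1 - cohort.outcomes["sans"].mask.mean()
    sofas_missing = 1 - cohort.outcomes["sofas"].mask.mean()
    assert abs(saps_missing - 0.30) < 0.03
    assert abs(sans_missing - 0.30) < 0.03
    assert abs(sofas_missing - 0.34) < 0.03


def test_zero_missingness_gives_complete_cohort(small_complete_cohort):
    for ds in small_complete_cohort.outcomes.values():
        assert ds.mask.all()


def test_cohort_determinism():
    a = generate_cohort(default_config(n_subjects=80, seed=5))
    b = generate_cohort(default_config(n_subjects=80, seed=5))
    c = generate_cohort(default_config(n_subjects=80, seed=6))
    for name in a.outcomes:
        assert np.array_equal(a.outcomes[name].y, b.outcomes[name].y, equal_nan=True)
    assert not np.array_equal(
        a.outcomes["saps"].y, c.outcomes["saps"].y, equal_nan=True
    )


def test_values_respect_declared_ranges(small_complete_cohort):
    for name, ds in small_complete_cohort.outcomes.items():
        lo, hi = ds.value_range
        vals = ds.y[ds.mask]
        assert vals.min() >= lo
        if np.isfinite(hi):
            assert vals.max() <= hi


def test_item_tables_consistent_with_schedule(small_complete_cohort):
    items = small_complete_cohort.items["sans"]
    assert set(items["time_months"].unique()) == {18.0, 24.0}
    assert items["value"].between(0, 5).all()
    assert items["item"].nunique() == 5


def test_coupling_calibration_hits_target_rr():
    pi_a, pi_b = (0.32, 0.68), (0.57, 0.43)
    corr = calibrate_coupling(pi_a, pi_b, target_rr=2.23)
    assert implied_rr(corr, pi_a, pi_b) == pytest.approx(2.23, abs=0.02)


def test_infeasible_rr_target_raises_before_generation():
    with pytest.raises(ValueError, match="unreachable"):
        calibrate_coupling((0.5, 0.5), (0.5, 0.5), target_rr=50.0)


def test_true_class_coupling_reproduces_rr_magnitude():
    cohort = generate_cohort(default_config(n_subjects=20_000, seed=8))
    a = cohort.true_classes["saps"]
    b = cohort.true_classes["sofas"]
    p_worst_given_f = np.mean(b[a == 1] == 1)
    p_worst_given_sl = np.mean(b[a == 0] == 1)
    assert p_worst_given_f / p_worst_given_sl == pytest.approx(2.23, abs=0.15)
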