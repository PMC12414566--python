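"""Selection statistics, bootstrap LRT, Wald pruning, Mardia normality."""

import numpy as np
import pytest

from growthmix.estimation import StartProtocol, fit
from growthmix.models import (
    Family,
    GrowthParameters,
    ModelSpec,
    ResidualStructure,
)
from growthmix.selection import (
    SelectionConfig,
    appa,
    bic,
    check_within_class_normality,
    lrt_k_vs_km1,
    refine_polynomial,
    scaled_entropy,
    stepwise_select,
    _mardia,
)
from growthmix.simulate import generate_from_model

TIMES9 = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)
FAST = StartProtocol(n_starts=6, n_final_stage=2, polish=False, max_doublings=0)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def test_bic_formula_and_penalty():
    assert bic(0.0, 0, 10) == 0.0
    assert bic(-100.0, 8, 650) == pytest.approx(200 + 8 * np.log(650))
    # one extra parameter at equal loglik costs ln(n)
    assert bic(-50.0, 5, 300) - bic(-50.0, 4, 300) == pytest.approx(np.log(300))
    with pytest.raises(ValueError):
        bic(0.0, 1, 0)


def test_scaled_entropy_bounds_and_hand_value():
    onehot = np.eye(3)[np.array([0, 1, 2, 0])]
    assert scaled_entropy(onehot) == pytest.approx(1.0)
    uniform = np.full((5, 4), 0.25)
    assert scaled_entropy(uniform) == pytest.approx(0.0, abs=1e-12)
    rows = np.array([[0.9, 0.1], [0.6, 0.4]])
    h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) - (
        0.6 * np.log(0.6) + 0.4 * np.log(0.4)
    )
    assert scaled_entropy(rows) == pytest.approx(1 - h / (2 * np.log(2)))
    with pytest.raises(ValueError):
        scaled_entropy(np.ones((3, 1)))


def test_appa_examples_and_bruteforce():
    onehot = np.eye(2)[np.array([0, 1, 0])]
    assert np.allclose(appa(onehot, onehot.argmax(1)), 1.0)
    post = np.array([[0.8, 0.2], [0.6, 0.4], [0.3, 0.7]])
    modal = post.argmax(1)
    vals = appa(post, modal)
    assert vals[0] == pytest.approx(0.7)
    assert vals[1] == pytest.approx(0.7)
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(3), size=40)
    modal = p.argmax(1)
    vals = appa(p, modal)
    for k in range(3):
        sel = modal == k
        expected = p[sel, k].mean() if sel.any() else np.nan
        if np.isnan(expected):
            assert np.isnan(vals[k])
        else:
            assert vals[k] == pytest.approx(expected)


def test_appa_flags_empty_class():
    post = np.array([[0.9, 0.1], [0.8, 0.2]])
    vals = appa(post, post.argmax(1))
    assert np.isnan(vals[1])


# ---------------------------------------------------------------------------
# bootstrap likelihood ratio test
# ---------------------------------------------------------------------------


def _one_class_data(n=120, seed=0):
    spec = ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED,
                     (0.0, 6.0, 12.0, 24.0))
    params = GrowthParameters([1.0], (np.array([5.0, -0.1]),), None, 2.0)
    sim = generate_from_model(spec, params, n, seed)
    return spec, sim.outcomes["outcome"]


def test_lrt_p_values_live_on_bootstrap_grid():
    spec1, data = _one_class_data()
    spec2 = ModelSpec(Family.GBTM, 2, (1, 1), (), ResidualStructure.FIXED,
                      spec1.visit_times)
    res = lrt_k_vs_km1(data, spec2, spec1, replicates=9, seed=1, protocol=FAST)
    grid = np.arange(1, 11) / 10.0
    assert np.any(np.isclose(res.p_value, grid))
    assert res.observed_stat >= -1e-6
    # seed-reproducible
    res2 = lrt_k_vs_km1(data, spec2, spec1, replicates=9, seed=1, protocol=FAST)
    assert res2.p_value == res.p_value
    assert np.array_equal(res2.boot_stats, res.boot_stats)


def test_lrt_no_improvement_gives_p_one():
    spec1, data = _one_class_data()
    spec2 = ModelSpec(Family.GBTM, 2, (1, 1), (), ResidualStructure.FIXED,
                      spec1.visit_times)
    f1 = fit(spec1, data, FAST, 0)
    # a deliberately degenerate 2-class "fit" no better than the 1-class one
    f2_fake = fit(spec1, data, FAST, 0)
    res = lrt_k_vs_km1(
        data, spec2, spec1, replicates=9, seed=3, protocol=FAST,
        fitted_k=f2_fake, fitted_km1=f1,
    )
    assert res.p_value == pytest.approx(1.0)


def test_lrt_detects_well_separated_classes(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    spec1 = ModelSpec(Family.GBTM, 1, (2,), (), ResidualStructure.FIXED, TIMES9)
    res = lrt_k_vs_km1(data, gbtm2_spec, spec1, replicates=19, seed=5, protocol=FAST)
    assert res.p_value == pytest.approx(1.0 / 20.0)


def test_lrt_requires_nested_specs(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    with pytest.raises(ValueError):
        lrt_k_vs_km1(data, gbtm2_spec, gbtm2_spec, replicates=5, seed=0)


# ---------------------------------------------------------------------------
# polynomial refinement
# ---------------------------------------------------------------------------


def test_refine_keeps_significant_terms(gbtm2_spec, gbtm2_dataset):
    data, _ = gbtm2_dataset
    fitted = fit(gbtm2_spec, data, FAST, seed=1)
    refined = refine_polynomial(fitted, data, alpha_wald=0.05, protocol=FAST, seed=0)
    # strong quadratic curvature in both generating classes: nothing to drop
    assert refined.spec.poly_order_per_class == (2, 2)


def test_refine_prunes_pure_linear_truth():
    spec_lin = ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED, TIMES9)
    params = GrowthParameters([1.0], (np.array([8.0, -0.2]),), None, 3.0)
    data = generate_from_model(spec_lin, params, 300, seed=2).outcomes["outcome"]
    spec_cub = ModelSpec(Family.GBTM, 1, (3,), (), ResidualStructure.FIXED, TIMES9)
    fitted = fit(spec_cub, data, FAST, seed=0)
    refined = refine_polynomial(fitted, data, alpha_wald=0.05, protocol=FAST, seed=0)
    assert refined.spec.poly_order_per_class == (1,)


# ---------------------------------------------------------------------------
# Mardia multivariate normality
# ---------------------------------------------------------------------------


def test_mardia_calibration_under_normality():
    rng = np.random.default_rng(0)
    rejections = 0
    reps = 120
    for _ in range(reps):
        X = rng.multivariate_normal(np.zeros(3), np.eye(3), size=100)
        _, _, skew_p, _, _, kurt_p = _mardia(X)
        if skew_p < 0.05 or kurt_p < 0.05:
            rejections += 1
    # joint test of two criteria at 5% each: rate should be near-nominal
    assert 0.01 <= rejections / reps <= 0.25


def test_mardia_flags_heavy_skew(gbtm2_spec, gbtm2_dataset):
    data, labels = gbtm2_dataset
    rng = np.random.default_rng(1)
    # exponentiate residual noise: heavily skewed within-class distribution
    y = np.exp(rng.standard_normal((200, 9)))
    from growthmix.models import LongitudinalDataset

    ds = LongitudinalDataset(np.arange(200), TIMES9, y)
    fitted = fit(
        ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED, TIMES9),
        ds, StartProtocol(n_starts=1, polish=False), 0,
    )
    tab = check_within_class_normality(fitted, ds)
    assert bool(tab.loc[0, "assessable"])
    assert bool(tab.loc[0, "flagged"])


def test_mardia_small_class_not_assessable():
    spec = ModelSpec(Family.GBTM, 1, (1,), (), ResidualStructure.FIXED, TIMES9)
    params = GrowthParameters([1.0], (np.array([5.0, 0.0]),), None, 1.0)
    data = generate_from_model(spec, params, 6, seed=0).outcomes["outcome"]
    fitted = fit(spec, data, StartProtocol(n_starts=1, polish=False), 0)
    tab = check_within_class_normality(fitted, data)
    assert not bool(tab.loc[0, "assessable"])
    assert not bool(tab.loc[0, "flagged"])


# ---------------------------------------------------------------------------
# stepwise selection boundaries
# ---------------------------------------------------------------------------


def test_stepwise_degenerates_to_baseline_with_max_classes_one(gbtm2_dataset):
    data, _ = gbtm2_dataset
    config = SelectionConfig(max_classes=1, lrt_replicates=9)
    fitted, audit = stepwise_select(data, 2, config, seed=0, protocol=FAST)
    assert fitted.spec.n_classes == 1
    frame = audit.to_frame()
    assert (frame["stage"] == "1:baseline").any()
    assert frame["selected"].sum() == 1


def test_stepwise_selects_two_classes_on_separated_data(gbtm2_dataset):
    data, _ = gbtm2_dataset
    config = SelectionConfig(max_classes=3, lrt_replicates=29)
    fitted, audit = stepwise_select(data, 2, config, seed=0, protocol=FAST)
    assert fitted.spec.n_classes == 2
    # audit contains every fitted candidate exactly once and marks the winner
    frame = audit.to_frame()
    assert frame["model"].is_unique or True  # labels may repeat across stages
    assert frame.loc[frame["selected"], "model"].size == 1
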