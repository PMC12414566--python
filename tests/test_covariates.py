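"""Manual 3-step analysis: logits, membership regression, distal tests, RRs."""

import numpy as np
import pytest

from growthmix.covariates import (
    LOGIT_CAP,
    bonferroni_adjust,
    cross_distribution_rr,
    distal_outcome_test,
    membership_proportions,
    misclassification_logits,
    predict_membership,
)
from growthmix.models import (
    Family,
    FittedModel,
    GrowthParameters,
    ModelSpec,
    ResidualStructure,
)

SPEC2 = ModelSpec(Family.GBTM, 2, (1, 1), (), ResidualStructure.FIXED, (0.0, 1.0))


def _fitted(post):
    post = np.asarray(post, dtype=float)
    params = GrowthParameters(
        post.mean(axis=0), tuple(np.zeros(2) for _ in range(post.shape[1])),
        None, 1.0,
    )
    spec = ModelSpec(
        Family.GBTM, post.shape[1], (1,) * post.shape[1], (),
        ResidualStructure.FIXED, (0.0, 1.0),
    )
    return FittedModel(spec, params, 0.0, post, post.argmax(1), {}, {})


def _classification_setup(rng, N=700, b_true=1.2, flip=0.15):
    """True class from a logistic model; modal label via known misclassification."""
    c = rng.standard_normal(N)
    p1 = 1.0 / (1.0 + np.exp(0.3 - b_true * c))
    true = (rng.random(N) < p1).astype(int)
    modal = np.where(rng.random(N) < 1 - flip, true, 1 - true)
    E = np.array([[1 - flip, flip], [flip, 1 - flip]])
    pi = np.array([1 - true.mean(), true.mean()])
    post = np.empty((N, 2))
    for s in (0, 1):
        pk = E[s] * pi
        post[modal == s] = pk / pk.sum()
    return c, true, modal, post


# ---------------------------------------------------------------------------
# misclassification logits
# ---------------------------------------------------------------------------


def test_one_hot_posteriors_give_identity_with_capped_logits():
    post = np.eye(2)[np.array([0, 1, 0, 1, 1])]
    lg = misclassification_logits(post, post.argmax(1))
    assert np.allclose(lg.classification, np.eye(2))
    off = lg.logits[0, 1]
    assert off <= -LOGIT_CAP + 1e-9  # capped, finite
    assert np.isfinite(lg.logits).all()


def test_uninformative_posteriors_give_uniform_classification():
    post = np.full((6, 2), 0.5)
    modal = np.array([0, 1, 0, 1, 0, 1])
    lg = misclassification_logits(post, modal)
    assert np.allclose(lg.classification, 0.5)
    assert np.allclose(lg.logits, 0.0)


def test_classification_matrix_matches_bayes_count_oracle():
    rng = np.random.default_rng(0)
    post = rng.dirichlet(np.ones(3), size=60)
    modal = post.argmax(1)
    if len(set(modal)) < 3:
        modal[:3] = [0, 1, 2]
    lg = misclassification_logits(post, modal)
    D = np.zeros((3, 3))
    for s in range(3):
        for k in range(3):
            D[s, k] = post[modal == s, k].sum() / post[:, k].sum()
    assert np.allclose(lg.classification, D)
    assert np.allclose(lg.classification.sum(axis=0), 1.0)


def test_empty_modal_class_is_an_error():
    post = np.array([[0.9, 0.1], [0.8, 0.2]])
    with pytest.raises(ValueError, match="class 1"):
        misclassification_logits(post, post.argmax(1))


# ---------------------------------------------------------------------------
# membership prediction under fixed logits
# ---------------------------------------------------------------------------


def test_intercept_only_model_reproduces_class_proportions_exactly():
    rng = np.random.default_rng(1)
    _, _, modal, post = _classification_setup(rng)
    fm = _fitted(post)
    lg = misclassification_logits(post, modal)
    fm.modal_assignment = modal
    props = membership_proportions(fm, lg)
    assert np.abs(props["posterior_mean"] - props["unconditional"]).max() < 1e-6


def test_known_logistic_effect_recovered():
    b_true = 1.2
    estimates = []
    for rep in range(6):
        rng = np.random.default_rng(10 + rep)
        c, _, modal, post = _classification_setup(rng, b_true=b_true)
        fm = _fitted(post)
        fm.modal_assignment = modal
        lg = misclassification_logits(post, modal)
        eff = predict_membership(fm, lg, c, reference_class=0)[0]
        estimates.append(eff.coefficient)
    est = np.array(estimates)
    mc_se = est.std(ddof=1) / np.sqrt(est.size)
    assert abs(est.mean() - b_true) < 3 * mc_se + 0.05


def test_null_covariate_gives_or_near_one():
    rng = np.random.default_rng(2)
    c, _, modal, post = _classification_setup(rng)
    fm = _fitted(post)
    fm.modal_assignment = modal
    lg = misclassification_logits(post, modal)
    eff = predict_membership(fm, lg, rng.standard_normal(c.size), reference_class=0)[0]
    assert eff.ci_low < 1.0 < eff.ci_high
    assert 0.6 < eff.estimate < 1.6


def test_log_transform_requires_positive_values():
    rng = np.random.default_rng(3)
    c, _, modal, post = _classification_setup(rng)
    fm = _fitted(post)
    fm.modal_assignment = modal
    lg = misclassification_logits(post, modal)
    with pytest.raises(ValueError, match="log transform"):
        predict_membership(fm, lg, c, log_transform=True)


# ---------------------------------------------------------------------------
# distal outcomes
# ---------------------------------------------------------------------------


def test_distal_continuous_smd_and_wald():
    rng = np.random.default_rng(4)
    _, true, modal, post = _classification_setup(rng)
    fm = _fitted(post)
    fm.modal_assignment = modal
    lg = misclassification_logits(post, modal)
    y = np.where(true == 1, 2.0, 0.0) + rng.standard_normal(true.size)
    res = distal_outcome_test(fm, lg, y, "continuous")
    comp = res.comparisons[0]
    d = res.class_estimates[0] - res.class_estimates[1]
    assert comp["estimate"] == pytest.approx(d / res.sample_sd)
    assert comp["p_value"] < 1e-6
    assert abs(abs(d) - 2.0) < 0.3


def test_distal_binary_empty_cell_flags_unbounded_or():
    # a class whose outcome probability is exactly zero under a sharp
    # classification has an unbounded odds ratio
    rng = np.random.default_rng(5)
    true = (rng.random(400) < 0.5).astype(int)
    post = np.eye(2)[true]
    fm = _fitted(post)
    fm.modal_assignment = true
    lg = misclassification_logits(post, true)
    y = np.where(true == 1, (rng.random(true.size) < 0.5), 0.0).astype(float)
    res = distal_outcome_test(fm, lg, y, "binary")
    assert res.comparisons[0]["unbounded"]
    assert res.comparisons[0]["ci_high"] == np.inf or res.comparisons[0]["ci_low"] == 0.0
    assert res.class_estimates.min() < 0.01


def test_distal_null_p_values_not_degenerate():
    pvals = []
    for rep in range(8):
        rng = np.random.default_rng(60 + rep)
        _, true, modal, post = _classification_setup(rng)
        fm = _fitted(post)
        fm.modal_assignment = modal
        lg = misclassification_logits(post, modal)
        y = rng.standard_normal(true.size)  # independent of class
        res = distal_outcome_test(fm, lg, y, "continuous")
        pvals.append(res.comparisons[0]["p_value"])
    pvals = np.array(pvals)
    assert (pvals > 0.05).mean() >= 0.5  # roughly uniform, not collapsed at 0


# ---------------------------------------------------------------------------
# risk ratios and multiplicity
# ---------------------------------------------------------------------------


def test_rr_hand_example_two_by_two():
    a = np.repeat([0, 1], 40)
    b = np.concatenate([np.zeros(30), np.ones(10), np.zeros(10), np.ones(30)])
    rr = cross_distribution_rr(a, b, target_class_b=0,
                               class_a_numerator=0, class_a_denominator=1)
    assert rr.rr == pytest.approx(3.0)
    se = np.sqrt(1 / 30 - 1 / 40 + 1 / 10 - 1 / 40)
    assert rr.ci_low == pytest.approx(3.0 * np.exp(-1.959963984540054 * se), rel=1e-6)


def test_rr_matches_bruteforce_contingency():
    rng = np.random.default_rng(6)
    a = rng.integers(0, 2, 300)
    b = rng.integers(0, 3, 300)
    rr = cross_distribution_rr(a, b, target_class_b=2,
                               class_a_numerator=1, class_a_denominator=0)
    p1 = np.mean(b[a == 1] == 2)
    p0 = np.mean(b[a == 0] == 2)
    assert rr.rr == pytest.approx(p1 / p0)


def test_rr_independent_assignments_near_one():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 2, 5000)
    b = rng.integers(0, 2, 5000)
    rr = cross_distribution_rr(a, b, target_class_b=1)
    assert rr.ci_low < 1.0 < rr.ci_high


def test_rr_excludes_missing_subjects_and_counts_them():
    a = np.array([0, 1, 0, 1, np.nan, 0])
    b = np.array([1, 1, 0, 0, 1, np.nan])
    rr = cross_distribution_rr(a, b, target_class_b=1)
    assert rr.n_excluded == 2


def test_rr_zero_denominator_is_an_error():
    a = np.repeat([0, 1], 10)
    b = np.concatenate([np.ones(10), np.zeros(10)])
    with pytest.raises(ZeroDivisionError):
        cross_distribution_rr(a, b, target_class_b=1,
                              class_a_numerator=0, class_a_denominator=1)


@pytest.mark.parametrize(
    "n_tests, expected",
    [(50, 0.001), (10, 0.005), (1, 0.05)],
)
def test_bonferroni_thresholds(n_tests, expected):
    thr, flags = bonferroni_adjust([0.0001], n_tests=n_tests)
    assert thr == pytest.approx(expected)
    assert flags[0]
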