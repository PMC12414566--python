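"""Manual 3-step association of trajectory membership with covariates.

After the unconditional growth model is selected (step 1), the
classification's misclassification error rates are extracted as fixed
logits (step 2), and covariates or distal outcomes are then modeled
against the latent classes with the measurement part held fixed at
those logits (step 3).  Fixing the logits accounts for classification
uncertainty while preventing the covariates from altering the class
structure: the modal classification entering step 3 is data and cannot
change.

Also provides cross-trajectory risk ratios (with Katz log-method
confidence intervals) and Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .models import FittedModel

__all__ = [
    "MisclassificationLogits",
    "CovariateEffect",
    "DistalResult",
    "RiskRatio",
    "misclassification_logits",
    "predict_membership",
    "distal_outcome_test",
    "cross_distribution_rr",
    "bonferroni_adjust",
]

LOGIT_CAP = 30.0  # finite stand-in for -inf logits under perfect classification
_Z95 = norm.ppf(0.975)


@dataclass
class MisclassificationLogits:
    """Fixed measurement model of step 3.

    ``classification[s, k]`` is P(modal class s | true class k), a
    column-stochastic matrix; ``logits[s, k]`` its logit
    parameterization against the reference modal class (last row),
    capped at +/- ``LOGIT_CAP`` where probabilities vanish.
    """

    classification: np.ndarray
    logits: np.ndarray
    reference_modal: int

    @property
    def n_classes(self) -> int:
        return self.classification.shape[0]

    def log_probabilities(self) -> np.ndarray:
        """Column-wise log P(modal s | true k) reconstructed from the logits."""
        return self.logits - logsumexp(self.logits, axis=0, keepdims=True)


def misclassification_logits(
    posteriors: np.ndarray, modal_assignment: np.ndarray
) -> MisclassificationLogits:
    """Extract the misclassification matrix from a fitted classification.

    The probability that a subject truly in class ``k`` is modally
    assigned to class ``s`` is estimated by weighting the modal
    indicator with the posteriors:
    ``P(s | k) = sum_{i: modal_i = s} p_ik / sum_i p_ik``.
    """
    p = np.asarray(posteriors, dtype=float)
    N, K = p.shape
    counts = np.bincount(modal_assignment, minlength=K)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"modal class {int(empty[0])} is empty")
    D = np.zeros((K, K))
    for s in range(K):
        D[s] = p[modal_assignment == s].sum(axis=0)
    D /= p.sum(axis=0)[None, :]
    logD = np.log(np.maximum(D, np.exp(-LOGIT_CAP)))
    logits = logD - logD[-1][None, :]
    logits = np.clip(logits, -LOGIT_CAP, LOGIT_CAP)
    return MisclassificationLogits(
        classification=D, logits=logits, reference_modal=K - 1
    )


@dataclass
class CovariateEffect:
    """One class contrast of a step-3 covariate model."""

    covariate: str
    effect_scale: str  # "odds_ratio" | "smd"
    class_index: int
    reference_class: int
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float = np.nan
    se: float = np.nan
    transform: str | None = None
    unbounded: bool = False

    def __post_init__(self) -> None:
        if self.effect_scale == "odds_ratio" and not self.unbounded:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("confidence interval must contain the estimate")


# ---------------------------------------------------------------------------
# step-3 likelihood machinery
# ---------------------------------------------------------------------------


def _step3_membership_nll(x, c, w_onehot_logD, K, ref):
    """Negative log-likelihood and gradient of the fixed-logit membership model."""
    free = [k for k in range(K) if k != ref]
    a = np.zeros(K)
    b = np.zeros(K)
    a[free] = x[: K - 1]
    b[free] = x[K - 1 :]
    eta = a[None, :] + np.outer(c, b)  # (N, K)
    joint = eta + w_onehot_logD  # logD[w_i, k] pre-gathered
    lse_joint = logsumexp(joint, axis=1)
    lse_prior = logsumexp(eta, axis=1)
    nll = -(lse_joint - lse_prior).sum()
    post = np.exp(joint - lse_joint[:, None])
    prior = np.exp(eta - lse_prior[:, None])
    diff = post - prior  # (N, K)
    ga = -diff.sum(axis=0)[free]
    gb = -(c[:, None] * diff).sum(axis=0)[free]
    return nll, np.concatenate([ga, gb]), post, prior


def _numeric_hessian(f, x, eps=1e-5):
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps**2)
    return H


def predict_membership(
    fitted: FittedModel,
    logits: MisclassificationLogits,
    covariate_values,
    reference_class: int | None = None,
    covariate_name: str = "covariate",
    log_transform: bool = False,
) -> list[CovariateEffect]:
    """Multinomial logistic regression of latent class on one covariate.

    The measurement part is fixed at ``logits`` so the class structure
    is maintained; intercepts and one slope per non-reference class are
    estimated by maximum likelihood.  Returns one odds-ratio contrast
    per non-reference class with Wald CI and p-value.  Subjects with a
    missing covariate are dropped.  Complete separation is flagged and
    the interval reported as unbounded.
    """
    K = logits.n_classes
    ref = K - 1 if reference_class is None else int(reference_class)
    w = np.asarray(fitted.modal_assignment)
    c = np.asarray(covariate_values, dtype=float)
    keep = np.isfinite(c)
    c, w = c[keep], w[keep]
    if log_transform:
        if np.any(c <= 0):
            raise ValueError("log transform requires strictly positive values")
        c = np.log(c)
    c_mean, c_sd = c.mean(), c.std() or 1.0
    cz = (c - c_mean) / c_sd  # standardized internally for conditioning
    logD = logits.log_probabilities()
    wlogD = logD[w]  # (N, K)

    pi_hat = np.maximum(fitted.params.class_proportions, 1e-10)
    free = [k for k in range(K) if k != ref]
    x0 = np.concatenate([np.log(pi_hat[free]) - np.log(pi_hat[ref]), np.zeros(K - 1)])

    def obj(x):
        nll, g, _, _ = _step3_membership_nll(x, cz, wlogD, K, ref)
        return nll, g

    res = minimize(obj, x0, jac=True, method="L-BFGS-B")
    x = res.x
    H = _numeric_hessian(lambda v: _step3_membership_nll(v, cz, wlogD, K, ref)[0], x)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(x.size, np.inf)

    effects = []
    for j, k in enumerate(free):
        b = x[K - 1 + j] / c_sd  # back to the covariate's own scale
        se = ses[K - 1 + j] / c_sd
        unbounded = not np.isfinite(se) or abs(b) > 15.0
        z = b / se if se > 0 and np.isfinite(se) else np.inf
        p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
        if unbounded:
            lo, hi = 0.0, np.inf
        else:
            lo, hi = np.exp(b - _Z95 * se), np.exp(b + _Z95 * se)
        effects.append(
            CovariateEffect(
                covariate=covariate_name,
                effect_scale="odds_ratio",
                class_index=k,
                reference_class=ref,
                estimate=float(np.exp(b)) if abs(b) < 700 else np.inf,
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(p),
                coefficient=float(b),
                se=float(se),
                transform="log" if log_transform else None,
                unbounded=bool(unbounded),
            )
        )
    return effects


def membership_proportions(
    fitted: FittedModel,
    logits: MisclassificationLogits,
    covariate_values=None,
) -> dict:
    """Class distribution of the step-3 model, for the invariance audit.

    Returns the modal class distribution (fixed data in step 3) and the
    model-implied posterior-mean proportions of the intercept-only (or
    covariate) fixed-logit model.
    """
    K = logits.n_classes
    w = np.asarray(fitted.modal_assignment)
    N = w.size
    modal = np.bincount(w, minlength=K) / N
    logD = logits.log_probabilities()
    wlogD = logD[w]
    c = (
        np.zeros(N)
        if covariate_values is None
        else np.asarray(covariate_values, dtype=float)
    )
    ref = K - 1
    pi_hat = np.maximum(fitted.params.class_proportions, 1e-10)
    x0 = np.concatenate(
        [np.log(pi_hat[:-1]) - np.log(pi_hat[-1]), np.zeros(K - 1)]
    )
    res = minimize(
        lambda x: _step3_membership_nll(x, c, wlogD, K, ref)[:2],
        x0, jac=True, method="L-BFGS-B",
    )
    _, _, post, prior = _step3_membership_nll(res.x, c, wlogD, K, ref)
    return {
        "modal": modal,
        "posterior_mean": post.mean(axis=0),
        "prior_mean": prior.mean(axis=0),
        "unconditional": fitted.params.class_proportions,
    }


# ---------------------------------------------------------------------------
# distal outcomes
# ---------------------------------------------------------------------------


@dataclass
class DistalResult:
    """Class-specific distal-outcome estimates and pairwise Wald tests."""

    outcome: str
    kind: str  # "continuous" | "binary"
    class_estimates: np.ndarray  # means (continuous) or probabilities (binary)
    sample_sd: float | None
    comparisons: list = field(default_factory=list)  # CovariateEffect-like rows
    overall_wald: float | None = None
    overall_p: float | None = None


_BINARY_CAP = 15.0


def distal_outcome_test(
    fitted: FittedModel,
    logits: MisclassificationLogits,
    outcome_values,
    outcome_kind: str,
    outcome_name: str = "distal",
    reference_class: int | None = None,
) -> DistalResult:
    """Wald mean/threshold equality tests of a distal outcome across classes.

    The distal outcome is added to the fixed-logit model with
    class-specific means (continuous, common variance) or class-specific
    log-odds (binary); pairwise Wald chi-square tests compare all class
    pairs.  Continuous effects are standardized mean differences (class
    mean difference over the sample standard deviation); binary effects
    are odds ratios.  A class with an empty outcome cell yields a
    flagged unbounded odds ratio.
    """
    if outcome_kind not in ("continuous", "binary"):
        raise ValueError("outcome_kind must be 'continuous' or 'binary'")
    K = logits.n_classes
    ref = K - 1 if reference_class is None else int(reference_class)
    w = np.asarray(fitted.modal_assignment)
    y = np.asarray(outcome_values, dtype=float)
    keep = np.isfinite(y)
    y, w = y[keep], w[keep]
    logD = logits.log_probabilities()
    wlogD = logD[w]

    pi_hat = np.maximum(fitted.params.class_proportions, 1e-10)
    a0 = np.log(pi_hat[:-1]) - np.log(pi_hat[-1])

    if outcome_kind == "continuous":
        mu0 = np.full(K, y.mean())
        x0 = np.concatenate([a0, mu0, [np.log(y.std() or 1.0)]])

        def nll(x):
            a = np.concatenate([x[: K - 1], [0.0]])
            m = x[K - 1 : 2 * K - 1]
            s = np.exp(x[-1])
            dens = norm.logpdf(y[:, None], loc=m[None, :], scale=s)
            joint = a[None, :] + wlogD + dens
            return -(logsumexp(joint, axis=1) - logsumexp(a)).sum()

        bounds = None
        sl = slice(K - 1, 2 * K - 1)
    else:
        q = np.clip(np.array([y[w == k].mean() if (w == k).any() else y.mean()
                              for k in range(K)]), 1e-4, 1 - 1e-4)
        lam0 = np.log(q / (1 - q))
        x0 = np.concatenate([a0, lam0])

        def nll(x):
            a = np.concatenate([x[: K - 1], [0.0]])
            lam = x[K - 1 :]
            logp1 = -np.logaddexp(0.0, -lam)
            logp0 = -np.logaddexp(0.0, lam)
            dens = y[:, None] * logp1[None, :] + (1 - y[:, None]) * logp0[None, :]
            joint = a[None, :] + wlogD + dens
            return -(logsumexp(joint, axis=1) - logsumexp(a)).sum()

        bounds = [(None, None)] * (K - 1) + [(-_BINARY_CAP, _BINARY_CAP)] * K
        sl = slice(K - 1, 2 * K - 1)

    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    x = res.x
    H = _numeric_hessian(nll, x, eps=1e-4)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.full((x.size, x.size), np.nan)
    est = x[sl]
    cov = cov_full[sl.start : sl.stop, sl.start : sl.stop]

    if outcome_kind == "continuous":
        class_est = est
        sample_sd = float(y.std(ddof=1))
    else:
        class_est = 1.0 / (1.0 + np.exp(-est))
        sample_sd = None

    if outcome_kind == "binary":
        # an (effectively) empty outcome cell makes the class's odds
        # unbounded; the log-odds likelihood is flat toward the boundary, so
        # probe the capped value directly instead of trusting the optimizer
        at_cap = np.abs(est) >= _BINARY_CAP - 1e-6
        nll_hat = nll(x)
        for k in range(K):
            for bound in (-_BINARY_CAP, _BINARY_CAP):
                xb = x.copy()
                xb[K - 1 + k] = bound
                if nll(xb) <= nll_hat + 1e-6:
                    at_cap[k] = True
    else:
        at_cap = np.zeros(K, dtype=bool)

    comparisons = []
    pairs = [(j, k) for j in range(K) for k in range(j + 1, K)]
    for j, k in pairs:
        d = est[j] - est[k]
        var = cov[j, j] + cov[k, k] - 2 * cov[j, k]
        unbounded = bool(at_cap[j] or at_cap[k]) or not np.isfinite(var) or var <= 0
        if unbounded:
            wald, p, se = np.inf, 0.0, np.inf
        else:
            se = np.sqrt(var)
            wald = d**2 / var
            p = float(2.0 * norm.sf(abs(d) / se))
        if outcome_kind == "continuous":
            effect = d / sample_sd
            lo, hi = (
                (d - _Z95 * se) / sample_sd,
                (d + _Z95 * se) / sample_sd,
            ) if np.isfinite(se) else (-np.inf, np.inf)
            scale = "smd"
        else:
            effect = float(np.exp(d)) if abs(d) < 700 else np.inf
            lo, hi = (
                (np.exp(d - _Z95 * se), np.exp(d + _Z95 * se))
                if np.isfinite(se)
                else (0.0, np.inf)
            )
            scale = "odds_ratio"
        comparisons.append(
            {
                "pair": (j, k),
                "effect_scale": scale,
                "estimate": float(effect),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "wald_stat": float(wald),
                "p_value": p,
                "unbounded": unbounded,
            }
        )

    # overall equality test across all classes
    C = np.zeros((K - 1, K))
    C[:, 0] = 1.0
    C[np.arange(K - 1), np.arange(1, K)] = -1.0
    diffs = C @ est
    Vc = C @ cov @ C.T
    try:
        overall = float(diffs @ np.linalg.solve(Vc, diffs))
        from scipy.stats import chi2 as _chi2

        overall_p = float(_chi2.sf(overall, K - 1))
    except np.linalg.LinAlgError:
        overall, overall_p = np.nan, np.nan

    return DistalResult(
        outcome=outcome_name,
        kind=outcome_kind,
        class_estimates=class_est,
        sample_sd=sample_sd,
        comparisons=comparisons,
        overall_wald=overall,
        overall_p=overall_p,
    )


# ---------------------------------------------------------------------------
# cross-trajectory risk ratios
# ---------------------------------------------------------------------------


@dataclass
class RiskRatio:
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    table: pd.DataFrame
    n_excluded: int


def cross_distribution_rr(
    assignment_a,
    assignment_b,
    target_class_b: int,
    class_a_numerator: int = 0,
    class_a_denominator: int = 1,
    posteriors_a: np.ndarray | None = None,
    posteriors_b: np.ndarray | None = None,
) -> RiskRatio:
    """Risk ratio of membership in ``target_class_b`` across two A classes.

    ``RR = P(B = target | A = numerator) / P(B = target | A = denominator)``
    over subjects present in both assignments (missing entries, coded as
    negative or NaN, are excluded and counted).  The 95% CI uses the
    Katz log method.  Passing posteriors switches to a
    posterior-weighted cross-tabulation (secondary mode); the default is
    the modal cross-tabulation.
    """
    a = np.asarray(assignment_a, dtype=float)
    b = np.asarray(assignment_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("assignments must cover the same subjects")
    keep = np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
    n_excluded = int((~keep).sum())
    a, b = a[keep].astype(int), b[keep].astype(int)

    Ka, Kb = a.max() + 1, b.max() + 1
    if posteriors_a is not None and posteriors_b is not None:
        table = posteriors_a[keep].T @ posteriors_b[keep]
    else:
        table = np.zeros((Ka, Kb))
        np.add.at(table, (a, b), 1.0)
    tab = pd.DataFrame(table)

    n1 = table[class_a_numerator].sum()
    n2 = table[class_a_denominator].sum()
    x1 = table[class_a_numerator, target_class_b]
    x2 = table[class_a_denominator, target_class_b]
    if n1 == 0 or n2 == 0 or x2 == 0:
        raise ZeroDivisionError(
            "zero cell in the risk-ratio denominator; RR undefined"
        )
    p1, p2 = x1 / n1, x2 / n2
    rr = p1 / p2
    if x1 == 0:
        return RiskRatio(0.0, 0.0, np.nan, np.nan, tab, n_excluded)
    se = np.sqrt(1.0 / x1 - 1.0 / n1 + 1.0 / x2 - 1.0 / n2)
    lo, hi = np.exp(np.log(rr) - _Z95 * se), np.exp(np.log(rr) + _Z95 * se)
    z = np.log(rr) / se
    return RiskRatio(
        rr=float(rr),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(2.0 * norm.sf(abs(z))),
        table=tab,
        n_excluded=n_excluded,
    )


def bonferroni_adjust(p_values, n_tests: int | None = None, alpha: float = 0.05):
    """Bonferroni-corrected threshold and pass flags.

    ``threshold = alpha / n_tests`` (``n_tests`` defaults to the number
    of p-values); a test passes when ``p < threshold``.
    """
    p = np.asarray(p_values, dtype=float)
    n = int(n_tests) if n_tests is not None else p.size
    if n < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n
    return threshold, p < threshold
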