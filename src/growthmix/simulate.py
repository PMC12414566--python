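"""Synthetic longitudinal cohorts with known latent-trajectory structure.

Two simulators are provided:

* :func:`generate_from_model` draws exactly from a given latent growth
  model (class from the mixing proportions, random effects and
  residuals Gaussian, no missingness) — the exact simulator used for
  parameter-recovery tests and the parametric bootstrap LRT.
* :func:`generate_cohort` emulates a 2-year first-episode-psychosis
  early-intervention cohort: three linked outcomes (positive-symptom
  sum over 9 visits, negative-symptom sum over 9 visits, functioning
  over 3 visits), latent classes coupled across outcomes through a
  shared Gaussian propensity, covariates and distal outcomes drawn
  class-conditionally, missing-at-random assessments whose hazard rises
  with time and depends only on an observed baseline covariate, and
  ground-truth class labels and clinical-endpoint flags for every
  subject.

Default mean curves interpolate the published trajectory anchors
(positive symptoms: 3.0 -> ~0.8 vs 9.8 -> 4.2; negative symptoms:
~9.2-9.8 start, ends 4.8/5.7/6.8; functioning: 44.2 -> 76.4 vs
35.9 -> 50), class proportions are 32/68, 41/15/44 and 57/43, and the
cross-outcome coupling is calibrated by bisection so that worse symptom
classes imply worse functioning at published risk-ratio magnitudes
(2.23 and 1.53).  Within-class variances are free parameters of the
generator, chosen to keep classification entropy in a realistic
0.4-0.8 band.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, norm

from .models import (
    Family,
    GrowthParameters,
    LongitudinalDataset,
    ModelSpec,
    ResidualStructure,
    class_mean_trajectory,
    design_matrix,
    random_effect_design,
)

__all__ = [
    "CohortConfig",
    "OutcomeConfig",
    "CovariateSpec",
    "DistalSpec",
    "SyntheticCohort",
    "curve_from_anchors",
    "generate_from_model",
    "generate_cohort",
    "default_config",
    "calibrate_coupling",
]

SYMPTOM_VISITS = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)
FUNCTIONING_VISITS = (0.0, 12.0, 24.0)

# global-item shares used to split a symptom sum into item scores
_SAPS_ITEM_SHARES = (0.30, 0.30, 0.20, 0.20)
_SANS_ITEM_SHARES = (0.20, 0.20, 0.20, 0.20, 0.20)  # last item = attention


def curve_from_anchors(anchor_points, poly_order: int) -> np.ndarray:
    """Least-squares polynomial coefficients through ``(time, value)`` anchors.

    With exactly ``poly_order + 1`` anchors the fitted curve passes
    through them exactly; with more anchors it is the ordinary
    least-squares polynomial.  Fewer anchors than coefficients is an
    error (underdetermined).
    """
    pts = np.asarray(anchor_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("anchor_points must be a sequence of (time, value) pairs")
    if pts.shape[0] < poly_order + 1:
        raise ValueError(
            f"need at least {poly_order + 1} anchors for order {poly_order}"
        )
    X = design_matrix(pts[:, 0], poly_order)
    coef, *_ = np.linalg.lstsq(X, pts[:, 1], rcond=None)
    return coef


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class OutcomeConfig:
    """Generating latent growth structure for one outcome.

    Classes are indexed from best (0) to worst (K-1) along the shared
    severity propensity.  ``anchors`` give per-class (time, value)
    points; the generating mean curve is the least-squares polynomial
    of ``poly_orders[k]`` through them.
    """

    name: str
    visit_times: tuple[float, ...]
    proportions: tuple[float, ...]
    poly_orders: tuple[int, ...]
    anchors: tuple[tuple[tuple[float, float], ...], ...]
    family: Family = Family.GBTM
    re_terms: tuple[str, ...] = ()
    re_sds: tuple[tuple[float, ...], ...] = ()  # per class (or single shared entry)
    residual_structure: ResidualStructure = ResidualStructure.FIXED
    residual_sd: object = 1.0  # scalar / per-time / per-class / (K,T), as SDs
    value_range: tuple[float, float] = (0.0, np.inf)
    truncate: bool = True
    propensity_loading: float | None = None  # set by calibration if None

    @property
    def n_classes(self) -> int:
        return len(self.proportions)

    def spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family,
            n_classes=self.n_classes,
            poly_order_per_class=self.poly_orders,
            random_effect_terms=self.re_terms,
            residual_structure=self.residual_structure,
            visit_times=self.visit_times,
        )

    def params(self) -> GrowthParameters:
        betas = tuple(
            curve_from_anchors(a, p) for a, p in zip(self.anchors, self.poly_orders)
        )
        re_cov = None
        if self.re_terms:
            mats = tuple(np.diag(np.asarray(s, dtype=float) ** 2) for s in self.re_sds)
            if self.family is Family.GMM_CLASS_VARIANT:
                if len(mats) == 1:
                    mats = mats * self.n_classes
                re_cov = mats
            else:
                re_cov = mats[0]
        sd = self.residual_sd
        if np.ndim(sd) == 0:
            theta = float(sd) ** 2
        else:
            theta = np.asarray(sd, dtype=float) ** 2
        return GrowthParameters(
            class_proportions=np.asarray(self.proportions, dtype=float),
            growth_coefficients=betas,
            re_covariance=re_cov,
            residual_variances=theta,
        )


@dataclass
class CovariateSpec:
    """Baseline covariate drawn conditionally on one outcome's true class.

    For a binary covariate ``values`` are per-class success
    probabilities; for a continuous one, per-class means (common
    ``sd``).  ``linked_outcome=None`` makes the covariate independent of
    every class (a null covariate).
    """

    name: str
    kind: str  # "binary" | "continuous"
    linked_outcome: str | None = None
    values: tuple[float, ...] = (0.5,)
    sd: float = 1.0

    def true_log_odds(self, class_proportions=None) -> np.ndarray | None:
        """Implied per-class membership log-odds vs class 0 (reference).

        For a binary covariate Bayes' rule gives the class-membership
        logit effect ``log[p_k (1 - p_0) / ((1 - p_k) p_0)]``; for a
        continuous covariate with common sd the effect per unit is
        ``(mu_k - mu_0) / sd^2``.
        """
        if self.linked_outcome is None:
            return None
        v = np.asarray(self.values, dtype=float)
        if self.kind == "binary":
            return np.log(v / (1 - v)) - np.log(v[0] / (1 - v[0]))
        return (v - v[0]) / self.sd**2


@dataclass
class DistalSpec:
    """Distal (end-of-follow-up) outcome drawn conditionally on a true class."""

    name: str
    kind: str  # "binary" | "continuous"
    linked_outcome: str
    values: tuple[float, ...] = (0.5,)
    sd: float = 1.0


@dataclass
class CohortConfig:
    """Full configuration of the synthetic cohort generator."""

    n_subjects: int = 689
    seed: int = 0
    outcomes: dict = field(default_factory=dict)
    covariates: list = field(default_factory=list)
    distal: list = field(default_factory=list)
    missing_rates: dict = field(default_factory=dict)  # per outcome, per visit
    missing_covariate: str | None = "neet"  # observed covariate in the MAR hazard
    missing_covariate_logit: float = 0.5
    rr_targets: dict = field(default_factory=dict)
    generate_items: bool = True

    def validate(self) -> None:
        for name, oc in self.outcomes.items():
            pi = np.asarray(oc.proportions)
            if np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
                raise ValueError(f"{name}: proportions must form a simplex")
            for a in oc.anchors:
                vals = np.asarray(a, dtype=float)[:, 1]
                lo, hi = oc.value_range
                if vals.min() < lo or vals.max() > hi:
                    raise ValueError(f"{name}: anchors outside value range")
        for name, rates in self.missing_rates.items():
            if len(rates) != len(self.outcomes[name].visit_times):
                raise ValueError(f"{name}: one missingness rate per visit required")


@dataclass
class SyntheticCohort:
    """Generated cohort: outcome datasets, ground truth, covariates, endpoints."""

    outcomes: dict
    true_classes: dict
    covariates: pd.DataFrame | None = None
    distal: pd.DataFrame | None = None
    true_endpoints: pd.DataFrame | None = None
    items: dict | None = None
    truncation_rates: dict | None = None
    config: CohortConfig | None = None

    def dataset(self, name: str) -> LongitudinalDataset:
        return self.outcomes[name]


# ---------------------------------------------------------------------------
# exact model-based simulator
# ---------------------------------------------------------------------------


def _draw_trajectories(spec, params, labels, rng, bounds=None):
    """Complete (n, T) outcome matrix for given class labels.

    With ``bounds`` the visit-level residual is drawn from a normal
    truncated so each value respects the score range — bounded scores
    without a point mass at the boundary.  Returns ``(y, clip_mass)``
    where ``clip_mass`` is the average probability mass truncated away
    (0 when ``bounds`` is None).
    """
    n = labels.size
    times = np.asarray(spec.visit_times)
    T = times.size
    theta = params.residual_table(spec)  # (K, T)
    y = np.empty((n, T))
    Z = random_effect_design(times, spec.random_effect_terms)
    covs = params.re_covariances(spec)
    clip_mass = 0.0
    for k in range(spec.n_classes):
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            continue
        mu = class_mean_trajectory(params, k, times)
        yk = np.tile(mu, (idx.size, 1))
        if spec.n_random_effects:
            # PSD but possibly singular covariance: eigen square root
            psi = covs[k]
            w_, V = np.linalg.eigh(psi)
            root = V * np.sqrt(np.maximum(w_, 0.0))
            b = rng.standard_normal((idx.size, psi.shape[0])) @ root.T
            yk += b @ Z.T
        sd = np.sqrt(theta[k])
        if bounds is None:
            yk += rng.standard_normal((idx.size, T)) * sd
        else:
            lo, hi = bounds
            a = (lo - yk) / sd
            b_ = ((hi - yk) / sd) if np.isfinite(hi) else np.full_like(yk, np.inf)
            u = rng.random((idx.size, T))
            lo_cdf, hi_cdf = norm.cdf(a), norm.cdf(b_)
            yk = yk + sd * norm.ppf(lo_cdf + u * (hi_cdf - lo_cdf))
            clip_mass += float((lo_cdf + (1.0 - hi_cdf)).sum())
        y[idx] = yk
    if bounds is not None:
        clip_mass /= n * T
    return y, clip_mass


def generate_from_model(
    spec: ModelSpec, params: GrowthParameters, n: int, seed
) -> SyntheticCohort:
    """Draw ``n`` complete subjects exactly from ``(spec, params)``.

    Class labels follow the mixing proportions, random effects are
    ``N(0, Psi_k)`` and residuals ``N(0, Theta_k)``.  No missingness is
    applied; output is deterministic given ``seed``.
    """
    params.validate(spec)
    rng = np.random.default_rng(seed)
    labels = rng.choice(spec.n_classes, size=n, p=params.class_proportions)
    y, _ = _draw_trajectories(spec, params, labels, rng)
    ds = LongitudinalDataset(
        subject_ids=np.arange(n),
        visit_times=spec.visit_times,
        y=y,
        outcome_name="outcome",
    )
    return SyntheticCohort(outcomes={"outcome": ds}, true_classes={"outcome": labels})


# ---------------------------------------------------------------------------
# cross-outcome coupling calibration
# ---------------------------------------------------------------------------


def _interval_probs(pi):
    """Standard-normal thresholds cutting the line into class intervals."""
    edges = norm.ppf(np.concatenate([[0.0], np.cumsum(pi)]))
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def _rect_prob(corr, a_lo, a_hi, b_lo, b_hi):
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, corr], [corr, 1.0]])

    def cdf(x, y):
        if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
            return 0.0
        return float(mvn.cdf([min(x, 38.0), min(y, 38.0)]))

    return cdf(a_hi, b_hi) - cdf(a_lo, b_hi) - cdf(a_hi, b_lo) + cdf(a_lo, b_lo)


def implied_rr(corr, pi_a, pi_b) -> float:
    """Risk ratio P(B = worst | A = worst) / P(B = worst | A = best).

    A and B memberships are threshold discretizations of standard
    normals with correlation ``corr``; "worst" is the last interval,
    "best" the first.
    """
    ea, eb = _interval_probs(pi_a), _interval_probs(pi_b)
    num = _rect_prob(corr, ea[-2], np.inf, eb[-2], np.inf) / pi_a[-1]
    den = _rect_prob(corr, -np.inf, ea[1], eb[-2], np.inf) / pi_a[0]
    return num / den


def calibrate_coupling(pi_a, pi_b, target_rr, tol=1e-4) -> float:
    """Bisect the latent correlation reproducing ``target_rr``.

    Raises ``ValueError`` when the target is unreachable with any
    correlation below 0.99 (infeasible configuration).
    """
    lo, hi = 0.0, 0.99
    if implied_rr(hi, pi_a, pi_b) < target_rr:
        raise ValueError(
            f"target RR {target_rr} unreachable given proportions {pi_a}, {pi_b}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if implied_rr(mid, pi_a, pi_b) < target_rr:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# default cohort configuration
# ---------------------------------------------------------------------------


def default_config(n_subjects: int = 689, seed: int = 0) -> CohortConfig:
    """Study-condition defaults: 689 subjects, published class topologies.

    Positive symptoms: 2-class class-variant GMM (cubic); negative
    symptoms: 3-class class-invariant GMM (cubic, cubic, linear);
    functioning: 2-class quadratic GBTM.  Missingness averages ~30% for
    the symptom schedules and ~34% for functioning.
    """
    saps = OutcomeConfig(
        name="saps",
        visit_times=SYMPTOM_VISITS,
        proportions=(0.32, 0.68),  # stable-low, fluctuating
        poly_orders=(3, 3),
        anchors=(
            ((0, 3.0), (1, 2.4), (2, 1.9), (3, 1.6), (6, 1.1), (9, 1.05),
             (12, 1.0), (18, 1.05), (24, 1.1)),
            ((0, 9.8), (1, 8.0), (2, 6.6), (3, 5.6), (6, 3.9), (9, 3.8),
             (12, 4.3), (18, 3.9), (24, 4.2)),
        ),
        family=Family.GMM_CLASS_VARIANT,
        re_terms=("intercept", "linear_slope"),
        re_sds=((0.3, 0.005), (0.4, 0.008)),
        residual_structure=ResidualStructure.FREE_BOTH,
        residual_sd=np.concatenate(
            [np.full((1, 9), 2.0), np.full((1, 9), 2.35)], axis=0
        ),
        value_range=(0.0, 20.0),
    )
    sans = OutcomeConfig(
        name="sans",
        visit_times=SYMPTOM_VISITS,
        proportions=(0.41, 0.15, 0.44),  # decreasing, fluctuating, stable-high
        poly_orders=(3, 3, 1),
        anchors=(
            # decreasing: steep improvement to month 6, flat thereafter
            ((0, 9.5), (1, 7.9), (2, 6.8), (3, 6.1), (6, 4.9), (9, 4.7),
             (12, 4.7), (18, 4.8), (24, 4.8)),
            # fluctuating: pronounced decrease-increase-decrease wave (the
            # curvature is what distinguishes this class from a level shift)
            ((0, 9.2), (6, 6.0), (14, 8.5), (24, 5.7)),
            ((0, 9.8), (24, 6.8)),
        ),
        family=Family.GMM_CLASS_INVARIANT,
        re_terms=("intercept", "linear_slope"),
        re_sds=((0.5, 0.02),),
        residual_structure=ResidualStructure.FREE_OVER_CLASSES,
        residual_sd=np.array([1.8, 1.9, 1.9]),
        value_range=(0.0, 25.0),
    )
    sofas = OutcomeConfig(
        name="sofas",
        visit_times=FUNCTIONING_VISITS,
        proportions=(0.57, 0.43),  # increasing, stable-moderate
        poly_orders=(2, 2),
        anchors=(
            ((0, 44.2), (12, 70.0), (24, 76.4)),
            ((0, 35.9), (12, 47.5), (24, 50.0)),
        ),
        family=Family.GBTM,
        residual_structure=ResidualStructure.FIXED,
        residual_sd=11.0,
        value_range=(0.0, 100.0),
    )
    # severity propensity runs best -> worst; SOFAS classes are ordered
    # best first, so worse functioning = last interval, matching symptoms.
    config = CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        outcomes={"saps": saps, "sans": sans, "sofas": sofas},
        covariates=[
            CovariateSpec("early_responder", "binary", "saps", (0.75, 0.40)),
            CovariateSpec("neet", "binary", "sofas", (0.60, 0.74)),
            CovariateSpec("premorbid_adjustment", "continuous", "sofas", (-0.3, 0.3), sd=1.0),
            CovariateSpec("noise_cov", "continuous", None, (0.0,), sd=1.0),
        ],
        distal=[
            DistalSpec("distal_severity", "continuous", "saps", (2.0, 5.0), sd=3.0),
            DistalSpec("distal_remission", "binary", "sofas", (0.62, 0.28)),
        ],
        missing_rates={
            "saps": [0.02, 0.18, 0.24, 0.26, 0.30, 0.34, 0.36, 0.44, 0.50],
            "sans": [0.02, 0.18, 0.24, 0.26, 0.30, 0.34, 0.36, 0.44, 0.50],
            "sofas": [0.04, 0.46, 0.54],
        },
        rr_targets={("saps", "sofas"): 2.23, ("sans", "sofas"): 1.53},
    )
    return config


# ---------------------------------------------------------------------------
# full cohort generator
# ---------------------------------------------------------------------------


def _resolve_loadings(config: CohortConfig) -> dict:
    """Per-outcome propensity loadings from the pairwise RR targets.

    The coupling between outcomes a and b is ``rho_a * rho_b``; with the
    default two targets sharing the functioning outcome, the symptom
    outcome of the first pair and functioning get equal loadings and the
    remaining outcome is solved from its own target.
    """
    loadings = {name: oc.propensity_loading for name, oc in config.outcomes.items()}
    targets = dict(config.rr_targets)
    if not targets:
        return {k: (v if v is not None else 0.0) for k, v in loadings.items()}
    (a0, b0), rr0 = next(iter(targets.items()))
    c0 = calibrate_coupling(
        config.outcomes[a0].proportions, config.outcomes[b0].proportions, rr0
    )
    if loadings.get(a0) is None:
        loadings[a0] = np.sqrt(c0)
    if loadings.get(b0) is None:
        loadings[b0] = c0 / loadings[a0]
    for (a, b), rr in list(targets.items())[1:]:
        c = calibrate_coupling(
            config.outcomes[a].proportions, config.outcomes[b].proportions, rr
        )
        known, unknown = (a, b) if loadings.get(a) is not None else (b, a)
        if loadings.get(unknown) is None:
            val = c / loadings[known]
            if not (0 <= val <= 0.999):
                raise ValueError(
                    f"RR target {rr} for ({a}, {b}) infeasible with current loadings"
                )
            loadings[unknown] = val
    return {k: (v if v is not None else 0.0) for k, v in loadings.items()}


def _class_conditional_draw(spec_values, kind, labels, sd, rng):
    vals = np.asarray(spec_values, dtype=float)
    if kind == "binary":
        return (rng.random(labels.size) < vals[labels]).astype(int)
    return vals[labels] + sd * rng.standard_normal(labels.size)


def _split_items(sums, shares, rng):
    """Split a symptom sum into bounded 0-5 global item scores."""
    shares = np.asarray(shares)
    base = sums[:, None] * shares[None, :]
    items = np.rint(base + 0.4 * rng.standard_normal(base.shape))
    return np.clip(items, 0, 5)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a linked three-outcome cohort with full ground truth.

    Deterministic given ``config.seed``.  See the module docstring for
    the generating process; :class:`SyntheticCohort` carries the masked
    outcome datasets, true class labels, covariate/distal tables, true
    endpoint flags and item-level symptom tables.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_ids = np.arange(n)

    loadings = _resolve_loadings(config)
    u = rng.standard_normal(n)  # shared severity propensity

    labels: dict[str, np.ndarray] = {}
    complete: dict[str, np.ndarray] = {}
    trunc_rates: dict[str, float] = {}
    for name, oc in config.outcomes.items():
        rho = loadings[name]
        v = rho * u + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal(n)
        edges = _interval_probs(np.asarray(oc.proportions))
        labels[name] = np.searchsorted(edges[1:-1], v)
        spec, params = oc.spec(), oc.params()
        bounds = oc.value_range if oc.truncate else None
        y, clip_mass = _draw_trajectories(spec, params, labels[name], rng, bounds)
        trunc_rates[name] = clip_mass
        complete[name] = y

    # covariates (class-conditional; must exist before the MAR mask)
    cov = pd.DataFrame({"subject_id": subject_ids})
    for cs in config.covariates:
        if cs.linked_outcome is None:
            if cs.kind == "binary":
                cov[cs.name] = (rng.random(n) < cs.values[0]).astype(int)
            else:
                cov[cs.name] = cs.values[0] + cs.sd * rng.standard_normal(n)
        else:
            cov[cs.name] = _class_conditional_draw(
                cs.values, cs.kind, labels[cs.linked_outcome], cs.sd, rng
            )

    # MAR missingness: per-visit base rate, shifted by an observed covariate
    masks: dict[str, np.ndarray] = {}
    shift = np.zeros(n)
    if config.missing_covariate and config.missing_covariate in cov.columns:
        c = cov[config.missing_covariate].to_numpy(dtype=float)
        shift = config.missing_covariate_logit * (c - c.mean())
    for name, oc in config.outcomes.items():
        rates = np.asarray(config.missing_rates.get(name, [0.0] * len(oc.visit_times)))
        rates = np.clip(rates, 1e-9, 1 - 1e-9)
        logit = np.log(rates / (1 - rates))[None, :] + shift[:, None]
        p_miss = 1.0 / (1.0 + np.exp(-logit))
        mask = rng.random((n, len(oc.visit_times))) >= p_miss  # True = observed
        none_obs = ~mask.any(axis=1)
        mask[none_obs, 0] = True  # keep at least the baseline visit
        masks[name] = mask

    # distal outcomes
    distal = pd.DataFrame({"subject_id": subject_ids})
    for ds_spec in config.distal:
        distal[ds_spec.name] = _class_conditional_draw(
            ds_spec.values, ds_spec.kind, labels[ds_spec.linked_outcome], ds_spec.sd, rng
        )

    # item-level symptom tables at the remission-window visits (18, 24)
    items: dict[str, pd.DataFrame] = {}
    item_values: dict[str, dict[float, np.ndarray]] = {}
    if config.generate_items:
        for name, shares in (("saps", _SAPS_ITEM_SHARES), ("sans", _SANS_ITEM_SHARES)):
            if name not in config.outcomes:
                continue
            times = config.outcomes[name].visit_times
            per_time = {}
            rows = []
            for t in (18.0, 24.0):
                ti = times.index(t)
                vals = _split_items(complete[name][:, ti], shares, rng)
                per_time[t] = vals
                observed = masks[name][:, ti]
                for j in range(len(shares)):
                    rows.append(
                        pd.DataFrame(
                            {
                                "subject_id": subject_ids[observed],
                                "time_months": t,
                                "item": j,
                                "value": vals[observed, j],
                            }
                        )
                    )
            items[name] = pd.concat(rows, ignore_index=True)
            item_values[name] = per_time

    true_endpoints = _true_endpoints(config, complete, item_values, subject_ids)

    outcomes = {}
    for name, oc in config.outcomes.items():
        y = complete[name].copy()
        y[~masks[name]] = np.nan
        outcomes[name] = LongitudinalDataset(
            subject_ids=subject_ids,
            visit_times=oc.visit_times,
            y=y,
            outcome_name=name,
            value_range=oc.value_range,
        )

    return SyntheticCohort(
        outcomes=outcomes,
        true_classes=labels,
        covariates=cov,
        distal=distal,
        true_endpoints=true_endpoints,
        items=items or None,
        truncation_rates=trunc_rates,
        config=config,
    )


def _true_endpoints(config, complete, item_values, subject_ids):
    """Ground-truth endpoint flags from the complete (pre-missingness) data.

    Independent of the endpoint-derivation module: plain array logic on
    the generator's own matrices.
    """
    out = pd.DataFrame({"subject_id": subject_ids})
    have_symptoms = "saps" in complete and "sans" in complete

    def _er(y, times):
        i0, i3 = times.index(0.0), times.index(3.0)
        base, m3 = y[:, i0], y[:, i3]
        with np.errstate(invalid="ignore"):
            flag = m3 <= 0.5 * base
        return np.where(base == 0, m3 == 0, flag)

    if "saps" in complete:
        t = config.outcomes["saps"].visit_times
        out["early_response_pos"] = _er(complete["saps"], list(t))
    if "sans" in complete:
        t = config.outcomes["sans"].visit_times
        out["early_response_neg"] = _er(complete["sans"], list(t))
    if have_symptoms:
        t = list(config.outcomes["saps"].visit_times)
        total = complete["saps"] + complete["sans"]
        out["early_response_total"] = _er(total, t)

    if item_values.get("saps"):
        iv = item_values["saps"]
        out["remission_pos"] = np.all(iv[18.0] <= 2, axis=1) & np.all(
            iv[24.0] <= 2, axis=1
        )
    if item_values.get("sans"):
        iv = item_values["sans"]
        core18, core24 = iv[18.0][:, :-1], iv[24.0][:, :-1]  # drop attention item
        out["remission_neg"] = np.all(core18 <= 2, axis=1) & np.all(core24 <= 2, axis=1)
    if "remission_pos" in out and "remission_neg" in out:
        out["clinical_remission"] = out["remission_pos"] & out["remission_neg"]
    if "sofas" in complete:
        t = list(config.outcomes["sofas"].visit_times)
        i12, i24 = t.index(12.0), t.index(24.0)
        y = complete["sofas"]
        out["functional_remission"] = (y[:, i12] > 60) & (y[:, i24] > 60)
    if "clinical_remission" in out and "functional_remission" in out:
        out["recovery"] = out["clinical_remission"] & out["functional_remission"]
    return out
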