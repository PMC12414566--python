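"""Latent growth model family for longitudinal trajectory analysis.

A latent growth model describes repeated measurements of an outcome
(e.g. a symptom-severity sum over a 2-year follow-up) as arising from
``K`` latent classes.  Within class ``k`` the mean trajectory is a
polynomial in time, subjects may deviate from it through Gaussian random
effects on the intercept and/or linear slope, and visit-level residuals
are Gaussian with a structure that may vary over time and/or classes.

Model families
--------------
GCM
    single-class growth curve model (the sample mean trajectory).
GBTM
    group-based trajectory model: latent classes, no random effects,
    one residual variance shared across time and classes.
LCGA
    latent class growth analysis: GBTM with the residual variance
    relaxed over time, classes, or both.
GMM (class-invariant / class-variant)
    growth mixture model: within-class random effects whose covariance
    is shared across classes or estimated per class.

Under missing-at-random data the subject-level likelihood integrates the
random effects analytically, so each subject contributes a multivariate
normal density restricted to their observed visits (full-information
maximum likelihood, FIML).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Family",
    "ResidualStructure",
    "ModelSpec",
    "GrowthParameters",
    "LongitudinalDataset",
    "FittedModel",
    "SingularCovarianceError",
    "count_parameters",
    "class_mean_trajectory",
    "component_logliks",
    "marginal_loglik",
    "class_posteriors",
    "design_matrix",
    "random_effect_design",
    "scale_time",
]

_LOG2PI = float(np.log(2.0 * np.pi))

# canonical ordering of random-effect terms
_RE_TERMS = ("intercept", "linear_slope")


class Family(str, enum.Enum):
    """Latent growth model family."""

    GCM = "GCM"
    GBTM = "GBTM"
    LCGA = "LCGA"
    GMM_CLASS_INVARIANT = "GMM_CLASS_INVARIANT"
    GMM_CLASS_VARIANT = "GMM_CLASS_VARIANT"


class ResidualStructure(str, enum.Enum):
    """How visit-level residual variances are structured."""

    FIXED = "FIXED"                      # one variance, all times and classes
    FREE_OVER_TIME = "FREE_OVER_TIME"    # one variance per visit
    FREE_OVER_CLASSES = "FREE_OVER_CLASSES"  # one variance per class
    FREE_BOTH = "FREE_BOTH"              # one variance per class and visit


class SingularCovarianceError(RuntimeError):
    """Raised when a per-subject marginal covariance is numerically singular."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of one latent growth model.

    Parameters
    ----------
    family : Family
        Model family; constrains the other fields (see below).
    n_classes : int
        Number of latent classes ``K`` (>= 1).
    poly_order_per_class : tuple of int
        Polynomial order of the mean trajectory per class, each in
        {1, 2, 3} (linear, quadratic, cubic).
    random_effect_terms : tuple of str
        Subset of ``("intercept", "linear_slope")``; empty for GBTM/LCGA.
    residual_structure : ResidualStructure
        Structure of the visit-level residual variances.
    visit_times : tuple of float
        Scheduled assessment times (months), strictly increasing.

    Notes
    -----
    Validity rules enforced at construction:

    * GCM implies ``n_classes == 1``.
    * GBTM implies no random effects and a FIXED residual; LCGA implies
      no random effects and a non-FIXED residual structure.
    * GMM families require at least one random-effect term;
      class-variant means one random-effect covariance per class.
    * ``poly_order + 1 <= len(visit_times)`` per class (identifiability):
      a quadratic needs >= 3 visits and a cubic >= 4.
    """

    family: Family
    n_classes: int
    poly_order_per_class: tuple[int, ...]
    random_effect_terms: tuple[str, ...] = ()
    residual_structure: ResidualStructure = ResidualStructure.FIXED
    visit_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(
            self, "residual_structure", ResidualStructure(self.residual_structure)
        )
        object.__setattr__(
            self, "poly_order_per_class", tuple(int(p) for p in self.poly_order_per_class)
        )
        # normalize RE term order to the canonical one
        terms = tuple(t for t in _RE_TERMS if t in self.random_effect_terms)
        if set(self.random_effect_terms) - set(_RE_TERMS):
            raise ValueError(
                f"unknown random-effect terms {set(self.random_effect_terms) - set(_RE_TERMS)}"
            )
        object.__setattr__(self, "random_effect_terms", terms)
        object.__setattr__(self, "visit_times", tuple(float(t) for t in self.visit_times))

        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.poly_order_per_class) != self.n_classes:
            raise ValueError("poly_order_per_class must have length n_classes")
        if any(p not in (1, 2, 3) for p in self.poly_order_per_class):
            raise ValueError("polynomial orders must be in {1, 2, 3}")
        if len(self.visit_times) < 2:
            raise ValueError("at least two visit times are required")
        if any(b <= a for a, b in zip(self.visit_times, self.visit_times[1:])):
            raise ValueError("visit_times must be strictly increasing")
        T = len(self.visit_times)
        for k, p in enumerate(self.poly_order_per_class):
            if p + 1 > T:
                raise ValueError(
                    f"class {k}: polynomial order {p} needs at least {p + 1} visits, "
                    f"schedule has {T}"
                )
        fam = self.family
        if fam is Family.GCM and self.n_classes != 1:
            raise ValueError("GCM is a single-class model")
        if fam in (Family.GBTM, Family.LCGA) and self.random_effect_terms:
            raise ValueError(f"{fam.value} admits no random effects")
        if fam is Family.GBTM and self.residual_structure is not ResidualStructure.FIXED:
            raise ValueError("GBTM uses a single FIXED residual variance; use LCGA to relax it")
        if fam is Family.LCGA and self.residual_structure is ResidualStructure.FIXED:
            raise ValueError("LCGA requires a relaxed residual structure")
        if fam in (Family.GMM_CLASS_INVARIANT, Family.GMM_CLASS_VARIANT):
            if not self.random_effect_terms:
                raise ValueError("GMM requires at least one random-effect term")

    # -- convenience -------------------------------------------------------

    @property
    def n_random_effects(self) -> int:
        return len(self.random_effect_terms)

    @property
    def has_random_effects(self) -> bool:
        return bool(self.random_effect_terms)

    @property
    def class_variant_re(self) -> bool:
        return self.family is Family.GMM_CLASS_VARIANT

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)


def count_parameters(spec: ModelSpec) -> int:
    """Number of free parameters of ``spec``.

    Fixed effects contribute ``order + 1`` per class; a random-effect
    covariance with ``r`` terms contributes ``r (r + 1) / 2`` (once if
    class-invariant, per class if class-variant); residual variances
    contribute 1, T, K or K*T depending on the structure; class
    proportions contribute ``K - 1``.
    """
    K = spec.n_classes
    T = spec.n_visits
    n = sum(p + 1 for p in spec.poly_order_per_class)
    r = spec.n_random_effects
    if r:
        cov_terms = r * (r + 1) // 2
        n += cov_terms * (K if spec.class_variant_re else 1)
    rs = spec.residual_structure
    n += {
        ResidualStructure.FIXED: 1,
        ResidualStructure.FREE_OVER_TIME: T,
        ResidualStructure.FREE_OVER_CLASSES: K,
        ResidualStructure.FREE_BOTH: K * T,
    }[rs]
    n += K - 1
    return n


def design_matrix(times: Sequence[float], order: int) -> np.ndarray:
    """Polynomial design matrix ``[1, t, ..., t^order]`` (len(times) x order+1)."""
    t = np.asarray(times, dtype=float)
    return np.vander(t, N=order + 1, increasing=True)


def random_effect_design(times: Sequence[float], terms: Sequence[str]) -> np.ndarray:
    """Random-effect design: columns for intercept (1) and/or linear slope (t)."""
    t = np.asarray(times, dtype=float)
    cols = []
    if "intercept" in terms:
        cols.append(np.ones_like(t))
    if "linear_slope" in terms:
        cols.append(t)
    if not cols:
        return np.zeros((t.size, 0))
    return np.column_stack(cols)


@dataclass
class GrowthParameters:
    """Free parameters of a latent growth model.

    Attributes
    ----------
    class_proportions : ndarray, shape (K,)
        Mixing proportions ``pi`` on the simplex.
    growth_coefficients : tuple of ndarray
        Per-class polynomial coefficients ``beta_k`` (outcome units per
        month^j), length ``poly_order_k + 1``.
    re_covariance : None, ndarray or tuple of ndarray
        Random-effect covariance ``Psi`` (r x r, PSD): ``None`` without
        random effects, a single matrix if class-invariant, one matrix
        per class if class-variant.
    residual_variances : float or ndarray
        Residual variances ``Theta`` in outcome-units^2: scalar (FIXED),
        shape (T,) (FREE_OVER_TIME), (K,) (FREE_OVER_CLASSES) or (K, T)
        (FREE_BOTH).
    """

    class_proportions: np.ndarray
    growth_coefficients: tuple[np.ndarray, ...]
    re_covariance: object = None
    residual_variances: object = 1.0

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        self.growth_coefficients = tuple(
            np.asarray(b, dtype=float) for b in self.growth_coefficients
        )
        if self.re_covariance is not None:
            if isinstance(self.re_covariance, (list, tuple)):
                self.re_covariance = tuple(
                    np.asarray(m, dtype=float) for m in self.re_covariance
                )
            else:
                self.re_covariance = np.asarray(self.re_covariance, dtype=float)
        if np.ndim(self.residual_variances) > 0:
            self.residual_variances = np.asarray(self.residual_variances, dtype=float)
        else:
            self.residual_variances = float(self.residual_variances)

    def validate(self, spec: ModelSpec, *, tol: float = 1e-10) -> None:
        """Check consistency with ``spec`` and the parameter-space invariants."""
        K = spec.n_classes
        pi = self.class_proportions
        if pi.shape != (K,):
            raise ValueError(f"class_proportions must have shape ({K},)")
        if np.any(pi < -tol) or abs(pi.sum() - 1.0) > tol:
            raise ValueError("class_proportions must be a probability simplex")
        if len(self.growth_coefficients) != K:
            raise ValueError("one coefficient vector per class is required")
        for k, b in enumerate(self.growth_coefficients):
            want = spec.poly_order_per_class[k] + 1
            if b.shape != (want,):
                raise ValueError(f"class {k}: expected {want} growth coefficients")
        r = spec.n_random_effects
        if r == 0:
            if self.re_covariance is not None:
                raise ValueError("spec has no random effects but re_covariance given")
        else:
            mats = self.re_covariances(spec)
            for k, m in enumerate(mats):
                if m.shape != (r, r):
                    raise ValueError(f"re_covariance {k} must be {r}x{r}")
                if not np.allclose(m, m.T, atol=1e-8):
                    raise ValueError(f"re_covariance {k} must be symmetric")
                ev = np.linalg.eigvalsh(m)
                if ev.min() < -1e-8 * max(1.0, ev.max()):
                    raise ValueError(f"re_covariance {k} must be PSD")
        theta = self.residual_table(spec)
        if np.any(theta <= 0):
            raise ValueError("all residual variances must be > 0")

    def re_covariances(self, spec: ModelSpec) -> tuple[np.ndarray, ...]:
        """Random-effect covariance per class (shared matrix repeated if invariant)."""
        if spec.n_random_effects == 0:
            return ()
        if isinstance(self.re_covariance, tuple):
            if len(self.re_covariance) != spec.n_classes:
                raise ValueError("class-variant re_covariance needs one matrix per class")
            return self.re_covariance
        return (self.re_covariance,) * spec.n_classes

    def residual_table(self, spec: ModelSpec) -> np.ndarray:
        """Residual variances broadcast to a (K, T) table."""
        K, T = spec.n_classes, spec.n_visits
        rs = spec.residual_structure
        th = self.residual_variances
        if rs is ResidualStructure.FIXED:
            return np.full((K, T), float(th))
        th = np.asarray(th, dtype=float)
        if rs is ResidualStructure.FREE_OVER_TIME:
            if th.shape != (T,):
                raise ValueError(f"FREE_OVER_TIME residuals must have shape ({T},)")
            return np.tile(th, (K, 1))
        if rs is ResidualStructure.FREE_OVER_CLASSES:
            if th.shape != (K,):
                raise ValueError(f"FREE_OVER_CLASSES residuals must have shape ({K},)")
            return np.tile(th[:, None], (1, T))
        if th.shape != (K, T):
            raise ValueError(f"FREE_BOTH residuals must have shape ({K}, {T})")
        return th.copy()


def class_mean_trajectory(
    params: GrowthParameters, class_index: int, times: Sequence[float]
) -> np.ndarray:
    """Mean outcome of class ``class_index`` at ``times``: sum_j beta_j t^j."""
    beta = params.growth_coefficients[class_index]
    return design_matrix(times, beta.size - 1) @ beta


def scale_time(
    spec: ModelSpec, params: GrowthParameters, factor: float
) -> GrowthParameters:
    """Re-express parameters fitted on time ``t' = t / factor`` in ``t`` units.

    Polynomial coefficient ``j`` divides by ``factor**j``; a linear-slope
    random effect divides by ``factor`` (its variance by ``factor**2``);
    residual variances are unchanged.
    """
    betas = tuple(
        b / factor ** np.arange(b.size) for b in params.growth_coefficients
    )
    re_cov = params.re_covariance
    if re_cov is not None:
        scale = np.ones(spec.n_random_effects)
        if "linear_slope" in spec.random_effect_terms:
            scale[-1] = 1.0 / factor
        D = np.diag(scale)
        if isinstance(re_cov, tuple):
            re_cov = tuple(D @ m @ D for m in re_cov)
        else:
            re_cov = D @ re_cov @ D
    return GrowthParameters(
        class_proportions=params.class_proportions.copy(),
        growth_coefficients=betas,
        re_covariance=re_cov,
        residual_variances=np.array(params.residual_variances)
        if np.ndim(params.residual_variances)
        else params.residual_variances,
    )


# ---------------------------------------------------------------------------
# longitudinal data container
# ---------------------------------------------------------------------------


@dataclass
class LongitudinalDataset:
    """Longitudinal outcome records on a fixed visit schedule.

    Stored wide: ``y[i, t]`` is subject ``i``'s value at scheduled visit
    ``t``, ``NaN`` where the assessment is missing.  Every subject must
    have at least one observed visit.
    """

    subject_ids: np.ndarray
    visit_times: tuple[float, ...]
    y: np.ndarray
    outcome_name: str = "outcome"
    value_range: tuple[float, float] = (-np.inf, np.inf)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.visit_times = tuple(float(t) for t in self.visit_times)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.subject_ids.size, len(self.visit_times)):
            raise ValueError("y must be (n_subjects, n_visits)")
        obs = ~np.isnan(self.y)
        if not obs.any(axis=1).all():
            bad = self.subject_ids[~obs.any(axis=1)]
            raise ValueError(f"subjects with no observed visits: {bad[:5].tolist()}")
        lo, hi = self.value_range
        vals = self.y[obs]
        if vals.size and (vals.min() < lo or vals.max() > hi):
            raise ValueError(
                f"{self.outcome_name}: values outside declared range {self.value_range}"
            )

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (N, T) observation mask (True = observed)."""
        return ~np.isnan(self.y)

    def missing_fraction(self) -> np.ndarray:
        """Per-subject fraction of scheduled visits missing."""
        return 1.0 - self.mask.mean(axis=1)

    def subset(self, indices: np.ndarray) -> "LongitudinalDataset":
        return LongitudinalDataset(
            subject_ids=self.subject_ids[indices],
            visit_times=self.visit_times,
            y=self.y[indices],
            outcome_name=self.outcome_name,
            value_range=self.value_range,
        )

    def with_time_factor(self, factor: float) -> "LongitudinalDataset":
        """Same data on the scaled schedule ``t / factor`` (optimizer conditioning)."""
        return LongitudinalDataset(
            subject_ids=self.subject_ids,
            visit_times=tuple(t / factor for t in self.visit_times),
            y=self.y,
            outcome_name=self.outcome_name,
            value_range=self.value_range,
        )

    def pattern_groups(self):
        """Subjects grouped by missingness pattern, batched by pattern size.

        Returns a list of dicts, one per distinct number of observed
        visits ``t``, with keys:

        ``obs``     (P, t) int array of observed visit indices per pattern
        ``subj``    (n,) subject indices, ordered by pattern
        ``pat_of``  (n,) pattern row (into ``obs``) of each subject
        ``y``       (n, t) observed values
        """
        if "groups" in self._cache:
            return self._cache["groups"]
        mask = self.mask
        # encode each row's pattern as bytes for grouping
        keys = np.packbits(mask, axis=1)
        _, pat_ids, inverse = np.unique(
            keys, axis=0, return_index=True, return_inverse=True
        )
        groups: dict[int, list] = {}
        for p, row in enumerate(pat_ids):
            obs_idx = np.flatnonzero(mask[row])
            subj = np.flatnonzero(inverse == p)
            groups.setdefault(obs_idx.size, []).append((obs_idx, subj))
        out = []
        for t, pats in sorted(groups.items()):
            obs = np.stack([o for o, _ in pats])
            subj = np.concatenate([s for _, s in pats])
            pat_of = np.concatenate(
                [np.full(s.size, j) for j, (_, s) in enumerate(pats)]
            )
            yobs = self.y[subj[:, None], obs[pat_of]]
            out.append({"obs": obs, "subj": subj, "pat_of": pat_of, "y": yobs})
        self._cache["groups"] = out
        return out


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


def component_logliks(
    spec: ModelSpec, params: GrowthParameters, data: LongitudinalDataset
) -> np.ndarray:
    """Per-subject, per-class Gaussian log-densities over observed visits.

    Returns the (N, K) matrix ``log f_k(y_i^obs)`` where
    ``f_k = N(X_i beta_k, Z_i Psi_k Z_i' + Theta_k)`` restricted to each
    subject's observed visits.  This is the FIML building block shared
    by the marginal likelihood, the posteriors, and the EM algorithm.
    """
    if data.n_visits != spec.n_visits or tuple(data.visit_times) != spec.visit_times:
        raise ValueError("dataset schedule does not match spec.visit_times")
    K = spec.n_classes
    N = data.n_subjects
    times = np.asarray(spec.visit_times)
    theta = params.residual_table(spec)  # (K, T)
    mus = np.stack(
        [class_mean_trajectory(params, k, times) for k in range(K)]
    )  # (K, T)

    out = np.empty((N, K))
    if not spec.has_random_effects:
        # diagonal covariance: fully vectorized over subjects
        mask = data.mask
        y0 = np.nan_to_num(data.y)
        for k in range(K):
            var = theta[k]  # (T,)
            r2 = (y0 - mus[k]) ** 2
            ll = -0.5 * (mask * (_LOG2PI + np.log(var)) + mask * r2 / var)
            out[:, k] = ll.sum(axis=1)
        return out

    Z = random_effect_design(times, spec.random_effect_terms)  # (T, r)
    covs = params.re_covariances(spec)
    for k in range(K):
        sigma_full = Z @ covs[k] @ Z.T + np.diag(theta[k])  # (T, T)
        mu = mus[k]
        for grp in data.pattern_groups():
            obs, subj, pat_of, yobs = grp["obs"], grp["subj"], grp["pat_of"], grp["y"]
            sig = sigma_full[obs[:, :, None], obs[:, None, :]]  # (P, t, t)
            sign, logdet = np.linalg.slogdet(sig)
            if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
                bad = int(np.flatnonzero(sign <= 0)[0]) if np.any(sign <= 0) else 0
                sid = data.subject_ids[subj[pat_of == bad][0]]
                raise SingularCovarianceError(
                    f"singular marginal covariance for subject {sid!r} in class {k}"
                )
            inv = np.linalg.inv(sig)
            r = yobs - mu[obs[pat_of]]
            maha = np.einsum("nt,ntu,nu->n", r, inv[pat_of], r)
            t = obs.shape[1]
            out[subj, k] = -0.5 * (t * _LOG2PI + logdet[pat_of] + maha)
    return out


def marginal_loglik(
    spec: ModelSpec, params: GrowthParameters, data: LongitudinalDataset
) -> float:
    """FIML marginal log-likelihood: sum_i log sum_k pi_k f_k(y_i^obs)."""
    cl = component_logliks(spec, params, data)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.class_proportions)
    return float(logsumexp(cl + logpi, axis=1).sum())


def class_posteriors(
    spec: ModelSpec, params: GrowthParameters, data: LongitudinalDataset
) -> np.ndarray:
    """Posterior class-membership probabilities ``p_ik`` (rows sum to 1).

    Computed in log space so that no row underflows to all zeros.
    """
    cl = component_logliks(spec, params, data)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.class_proportions)
    joint = cl + logpi
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    return post


@dataclass
class FittedModel:
    """A fitted latent growth model.

    Bundles the spec, the maximum-likelihood parameters, the
    log-likelihood, posterior classification, fit indices and the
    convergence report from the multistart protocol.  ``modal_assignment``
    breaks posterior ties toward the lowest class index.
    """

    spec: ModelSpec
    params: GrowthParameters
    loglik: float
    posteriors: np.ndarray
    modal_assignment: np.ndarray
    fit_indices: dict
    convergence_report: dict
    se_growth_coefficients: tuple[np.ndarray, ...] | None = None

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.modal_assignment, minlength=self.spec.n_classes)

    def refresh_classification(self, data: LongitudinalDataset) -> None:
        """Recompute posteriors and modal assignment from current parameters."""
        self.posteriors = class_posteriors(self.spec, self.params, data)
        self.modal_assignment = np.argmax(self.posteriors, axis=1)
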