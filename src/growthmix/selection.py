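"""Staged model building and selection for latent growth models.

The selection strategy fits increasingly less constrained models in
four stages and keeps, at every stage, the most parsimonious admissible
model by BIC:

1. a single-class growth curve model (the sample mean trajectory);
2. class enumeration with group-based trajectory models (K = 1..max);
3. relaxation of the residual variance over time, classes, or both;
4. addition of class-invariant then class-variant random effects on
   the intercept and linear slope.

Candidate admissibility combines a parametric bootstrap likelihood
ratio test of K vs K-1 classes, a hard minimum class share (default
5%), and advisory classification-quality floors (scaled entropy > 0.5,
APPA > 0.7) that are reported and can be made hard.  The winning model
is then refined by iteratively dropping the highest non-significant
polynomial term (Wald tests) and its classes are checked for
multivariate normality with Mardia's skewness/kurtosis test.

The published "adjusted LMR bootstrap likelihood ratio test" conflates
two distinct procedures; here the parametric bootstrap LRT is the
operative test and the naive -2*delta-log-likelihood is reported
alongside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2, norm

from .estimation import (
    EstimationError,
    StartProtocol,
    adapt_parameters,
    fit,
    multistart_replicated,
)
from .models import (
    Family,
    FittedModel,
    GrowthParameters,
    LongitudinalDataset,
    ModelSpec,
    ResidualStructure,
)

__all__ = [
    "SelectionConfig",
    "SelectionAudit",
    "AuditEntry",
    "LRTResult",
    "bic",
    "scaled_entropy",
    "appa",
    "lrt_k_vs_km1",
    "stepwise_select",
    "refine_polynomial",
    "check_within_class_normality",
    "permute_classes",
    "align_classes",
]


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian information criterion: ``-2 loglik + n_params ln(n)``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


def scaled_entropy(posteriors: np.ndarray) -> float:
    """Classification certainty in [0, 1]: ``1 - sum(-p ln p) / (N ln K)``.

    1 for a perfectly separated (one-hot) classification, 0 for a
    completely uninformative (uniform) one.  Undefined for K = 1.
    """
    p = np.asarray(posteriors, dtype=float)
    n, k = p.shape
    if k < 2:
        raise ValueError("scaled entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum()
    return float(1.0 - h / (n * np.log(k)))


def appa(posteriors: np.ndarray, modal_assignment: np.ndarray) -> np.ndarray:
    """Average posterior probability of assignment per class.

    ``APPA_k`` is the mean of ``p_ik`` over subjects modally assigned to
    class ``k``; ``NaN`` (flagged undefined) for empty classes.
    """
    p = np.asarray(posteriors, dtype=float)
    K = p.shape[1]
    out = np.full(K, np.nan)
    for k in range(K):
        sel = modal_assignment == k
        if sel.any():
            out[k] = p[sel, k].mean()
    return out


# ---------------------------------------------------------------------------
# class relabeling utilities
# ---------------------------------------------------------------------------


def permute_classes(fitted: FittedModel, perm) -> FittedModel:
    """Relabel classes of a fitted model by ``perm`` (new index k <- perm[k])."""
    perm = np.asarray(perm)
    spec = fitted.spec
    new_spec = dataclasses.replace(
        spec, poly_order_per_class=tuple(spec.poly_order_per_class[j] for j in perm)
    )
    p = fitted.params
    re_cov = p.re_covariance
    if isinstance(re_cov, tuple):
        re_cov = tuple(re_cov[j] for j in perm)
    theta = p.residual_variances
    if spec.residual_structure in (
        ResidualStructure.FREE_OVER_CLASSES,
        ResidualStructure.FREE_BOTH,
    ):
        theta = np.asarray(theta)[perm]
    new_params = GrowthParameters(
        class_proportions=p.class_proportions[perm],
        growth_coefficients=tuple(p.growth_coefficients[j] for j in perm),
        re_covariance=re_cov,
        residual_variances=theta,
    )
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    fi = dict(fitted.fit_indices)
    for key in ("appa", "class_counts", "class_proportions_modal"):
        if key in fi and fi[key] is not None:
            fi[key] = np.asarray(fi[key])[perm]
    se = fitted.se_growth_coefficients
    return FittedModel(
        spec=new_spec,
        params=new_params,
        loglik=fitted.loglik,
        posteriors=fitted.posteriors[:, perm],
        modal_assignment=inv[fitted.modal_assignment],
        fit_indices=fi,
        convergence_report=fitted.convergence_report,
        se_growth_coefficients=None if se is None else tuple(se[j] for j in perm),
    )


def align_classes(fitted: FittedModel, reference_assignment: np.ndarray) -> FittedModel:
    """Permute classes to best match a reference modal assignment.

    Uses the Hungarian algorithm on the assignment cross-tabulation so
    that class labels stay stable across refits.
    """
    K = fitted.spec.n_classes
    conf = np.zeros((K, K))
    for r, c in zip(reference_assignment, fitted.modal_assignment):
        conf[r, c] += 1
    row, col = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=int)
    perm[row] = col
    if np.array_equal(perm, np.arange(K)):
        return fitted
    return permute_classes(fitted, perm)


# ---------------------------------------------------------------------------
# bootstrap likelihood ratio test
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    """Parametric bootstrap likelihood-ratio test of K vs K-1 classes."""

    p_value: float
    observed_stat: float  # -2 (ll_{K-1} - ll_K)
    boot_stats: np.ndarray
    n_replicates: int
    n_failed: int

    def __repr__(self) -> str:  # compact, the boot stats can be long
        return (
            f"LRTResult(p={self.p_value:.4g}, stat={self.observed_stat:.3f}, "
            f"R={self.n_replicates}, failed={self.n_failed})"
        )


def _default_boot_protocol(protocol: StartProtocol) -> StartProtocol:
    # bootstrap refits only need a Delta-loglik, so a much lighter protocol
    # than the observed-data fits is standard
    return StartProtocol(
        n_starts=max(2, protocol.n_starts // 16),
        n_final_stage=1,
        stage1_iters=6,
        em_tol=1e-6,
        em_max_iter=120,
        polish=False,
        max_doublings=0,
    )


def lrt_k_vs_km1(
    data: LongitudinalDataset,
    spec_k: ModelSpec,
    spec_km1: ModelSpec,
    replicates: int,
    seed: int,
    protocol: StartProtocol | None = None,
    boot_protocol: StartProtocol | None = None,
    fitted_k: FittedModel | None = None,
    fitted_km1: FittedModel | None = None,
    max_failure_fraction: float = 0.10,
) -> LRTResult:
    """Parametric bootstrap LRT of ``spec_k`` against ``spec_km1``.

    ``replicates`` datasets are simulated from the fitted (K-1)-class
    model (complete data re-masked with the observed missingness
    pattern), both models are refitted on each, and the p-value is
    ``(1 + #{boot >= observed}) / (R + 1)``, so attainable p-values lie
    in ``{1/(R+1), ..., 1}``.  Seed-reproducible.
    """
    from .simulate import generate_from_model  # local: avoid import cycle

    if spec_km1.n_classes != spec_k.n_classes - 1:
        raise ValueError("spec_km1 must have exactly one class fewer than spec_k")
    protocol = protocol or StartProtocol()
    boot_protocol = boot_protocol or _default_boot_protocol(protocol)
    base = np.random.SeedSequence([seed, 0x1B7])
    seeds = base.spawn(2 * replicates + 2)
    if fitted_km1 is None:
        fitted_km1 = fit(spec_km1, data, protocol, seeds[-1])
    if fitted_k is None:
        fitted_k = fit(spec_k, data, protocol, seeds[-2])
    observed = 2.0 * (fitted_k.loglik - fitted_km1.loglik)

    mask = data.mask
    boot = []
    n_failed = 0
    for r in range(replicates):
        sim = generate_from_model(
            spec_km1, fitted_km1.params, data.n_subjects, seeds[2 * r]
        )
        y = sim.outcomes["outcome"].y.copy()
        y[~mask] = np.nan
        bdata = LongitudinalDataset(
            subject_ids=data.subject_ids,
            visit_times=data.visit_times,
            y=y,
            outcome_name=data.outcome_name,
        )
        try:
            b_km1 = fit(spec_km1, bdata, boot_protocol, seeds[2 * r + 1])
            b_k = fit(spec_k, bdata, boot_protocol, seeds[2 * r + 1])
            stat = 2.0 * (b_k.loglik - b_km1.loglik)
        except (EstimationError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        boot.append(max(stat, 0.0))
    if n_failed > max_failure_fraction * replicates:
        raise EstimationError(
            f"bootstrap LRT: {n_failed}/{replicates} replicate refits failed"
        )
    boot = np.asarray(boot)
    p = (1.0 + np.sum(boot >= observed)) / (boot.size + 1.0)
    return LRTResult(
        p_value=float(p),
        observed_stat=float(observed),
        boot_stats=boot,
        n_replicates=replicates,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# selection configuration and audit trail
# ---------------------------------------------------------------------------


@dataclass
class SelectionConfig:
    """Tuning constants of the staged selection procedure.

    ``min_class_proportion`` is the hard 5% rule; the entropy and APPA
    floors are advisory by default (recorded in the audit, enforced only
    when ``floors_hard``).  ``bic_tie_margin`` implements the
    parsimony tie-break: within this BIC margin the model with fewer
    parameters wins.
    """

    max_classes: int = 6
    min_class_proportion: float = 0.05
    entropy_floor: float = 0.5
    appa_floor: float = 0.7
    floors_hard: bool = False
    lrt_replicates: int = 99
    alpha_lrt: float = 0.05
    alpha_wald: float = 0.05
    bic_tie_margin: float = 2.0
    stop_enumeration_early: bool = True
    reassess_k: bool = True
    normality_min_class_size: int = 10

    def __post_init__(self) -> None:
        if self.max_classes < 1:
            raise ValueError("max_classes must be >= 1")
        if not (0 < self.min_class_proportion < 1):
            raise ValueError("min_class_proportion must be in (0, 1)")


@dataclass
class AuditEntry:
    stage: str
    label: str
    spec: ModelSpec | None
    n_params: int | None = None
    loglik: float | None = None
    bic: float | None = None
    entropy: float | None = None
    appa_min: float | None = None
    smallest_class_share: float | None = None
    lrt_p: float | None = None
    decision: str = ""
    reason: str = ""
    selected: bool = False


@dataclass
class SelectionAudit:
    """Ordered record of every candidate fitted during selection."""

    entries: list = field(default_factory=list)

    def add(self, entry: AuditEntry) -> None:
        self.entries.append(entry)

    def mark_selected(self, label: str) -> None:
        """Mark the final audit entry bearing ``label`` as the selected model."""
        for e in self.entries:
            e.selected = False
        for e in reversed(self.entries):
            if e.label == label:
                e.selected = True
                break

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "stage": e.stage,
                    "model": e.label,
                    "n_params": e.n_params,
                    "loglik": e.loglik,
                    "bic": e.bic,
                    "entropy": e.entropy,
                    "appa_min": e.appa_min,
                    "smallest_class_share": e.smallest_class_share,
                    "lrt_p": e.lrt_p,
                    "decision": e.decision,
                    "reason": e.reason,
                    "selected": e.selected,
                }
            )
        return pd.DataFrame(rows)


def _describe(fitted: FittedModel) -> dict:
    fi = fitted.fit_indices
    shares = fi["class_counts"] / fitted.posteriors.shape[0]
    ap = fi["appa"]
    return {
        "n_params": fi["n_params"],
        "loglik": fitted.loglik,
        "bic": fi["bic"],
        "entropy": fi["scaled_entropy"],
        "appa_min": float(np.nanmin(ap)) if ap is not None else None,
        "smallest_class_share": float(shares.min()),
    }


def _label(spec: ModelSpec) -> str:
    fam = spec.family.value
    orders = ",".join(str(p) for p in spec.poly_order_per_class)
    re = "+".join(spec.random_effect_terms) or "none"
    return f"{fam}/K={spec.n_classes}/orders={orders}/re={re}/res={spec.residual_structure.value}"


def _admissible(fitted: FittedModel, config: SelectionConfig, lrt_p=None):
    """(ok, reason) under the hard 5% rule, LRT, and optional hard floors."""
    d = _describe(fitted)
    if d["smallest_class_share"] < config.min_class_proportion:
        return False, (
            f"smallest class {d['smallest_class_share']:.1%} < "
            f"{config.min_class_proportion:.0%}"
        )
    if lrt_p is not None and lrt_p >= config.alpha_lrt:
        return False, f"LRT p={lrt_p:.3f} not significant"
    if config.floors_hard and fitted.spec.n_classes > 1:
        if d["entropy"] is not None and d["entropy"] <= config.entropy_floor:
            return False, f"entropy {d['entropy']:.2f} <= floor"
        if d["appa_min"] is not None and d["appa_min"] <= config.appa_floor:
            return False, f"APPA {d['appa_min']:.2f} <= floor"
    return True, "admissible"


def _pick_by_bic(candidates, margin):
    """BIC-minimal candidate; within ``margin`` prefer fewer parameters."""
    best_bic = min(f.fit_indices["bic"] for f in candidates)
    near = [f for f in candidates if f.fit_indices["bic"] <= best_bic + margin]
    near.sort(key=lambda f: (f.fit_indices["n_params"], f.fit_indices["bic"]))
    return near[0]


def _confirm_k(current, data, config, protocol, audit, seedseq, stage,
               fitter=None):
    """Re-compare the class count under the current within-class structure.

    Class enumeration happens under the most constrained (GBTM) model,
    where unmodeled residual heterogeneity or random effects can masquerade
    as extra classes.  Once the within-class structure has been relaxed,
    the chosen K is re-tested against K-1 (same family, orders, residual
    structure); the reduction is accepted whenever BIC (with the parsimony
    tie-break) prefers it, iterating down to a single class if supported.
    """
    seeds = seedseq.spawn(max(current.spec.n_classes, 1))
    step = 0
    while current.spec.n_classes > 1:
        spec = current.spec
        K = spec.n_classes
        spec_m = dataclasses.replace(
            spec,
            n_classes=K - 1,
            poly_order_per_class=spec.poly_order_per_class[: K - 1],
        )
        drop = int(np.argmin(current.params.class_proportions))
        warm = (adapt_parameters(spec, current.params, spec_m, drop_class=drop),)
        try:
            if fitter is None:
                reduced = multistart_replicated(
                    spec_m, data, protocol, _seed_int(seeds[step]), extra_inits=warm
                )
            else:
                reduced = fitter(spec_m, _seed_int(seeds[step]), warm)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            audit.add(AuditEntry(stage, _label(spec_m), spec_m,
                                 decision="failed", reason=str(exc)))
            break
        choice = _pick_by_bic([current, reduced], config.bic_tie_margin)
        kept = choice is reduced
        audit.add(
            AuditEntry(
                stage=stage, label=_label(spec_m), spec=spec_m,
                **_describe(reduced),
                decision="adopted" if kept else "rejected",
                reason=(
                    f"K={K - 1} preferred over K={K} under relaxed structure"
                    if kept
                    else f"K={K} confirmed against K={K - 1}"
                ),
            )
        )
        if not kept:
            break
        current = reduced
        step += 1
    return current


# ---------------------------------------------------------------------------
# four-stage selection
# ---------------------------------------------------------------------------


def stepwise_select(
    data: LongitudinalDataset,
    preset_poly_order: int,
    config: SelectionConfig | None = None,
    seed: int = 0,
    protocol: StartProtocol | None = None,
):
    """Run the four-stage model-building strategy on ``data``.

    Returns ``(FittedModel, SelectionAudit)``.  If no multi-class model
    is admissible the single-class baseline is returned and the audit
    explains every rejection.
    """
    config = config or SelectionConfig()
    protocol = protocol or StartProtocol()
    boot_protocol = _default_boot_protocol(protocol)
    audit = SelectionAudit()
    times = data.visit_times
    T = len(times)
    if preset_poly_order + 1 > T:
        raise ValueError(
            f"preset polynomial order {preset_poly_order} needs {preset_poly_order + 1} visits"
        )
    seedseq = {
        name: np.random.SeedSequence([seed, i])
        for i, name in enumerate(
            ["gcm", "enum", "lrt", "resid", "re", "refine", "extra"]
        )
    }

    def _fit(spec, ss, warm=()):
        return multistart_replicated(
            spec, data, protocol, _seed_int(ss), extra_inits=warm
        )

    def _screen(spec, ss, warm=()):
        # single-run fit for candidate screening; the eventual winner is
        # re-estimated with the full replicated protocol at the end
        return fit(spec, data, protocol, _seed_int(ss), extra_inits=warm)

    # ---- stage 1: single-class growth curve baseline ----------------------
    gcm_spec = ModelSpec(
        family=Family.GCM,
        n_classes=1,
        poly_order_per_class=(preset_poly_order,),
        random_effect_terms=("intercept", "linear_slope"),
        residual_structure=ResidualStructure.FIXED,
        visit_times=times,
    )
    gcm = _fit(gcm_spec, seedseq["gcm"])
    audit.add(
        AuditEntry(
            stage="1:baseline", label=_label(gcm_spec), spec=gcm_spec,
            **_describe(gcm), decision="baseline", reason="sample mean trajectory",
        )
    )

    # ---- stage 2: GBTM class enumeration -----------------------------------
    # All class counts are fitted first; the bootstrap LRT (the expensive
    # gate) is then evaluated lazily, only for the BIC-preferred K, walking
    # down while the test is non-significant.
    enum_fits = {}
    enum_admissible = {}
    enum_seeds = seedseq["enum"].spawn(config.max_classes)
    lrt_seeds = seedseq["lrt"].spawn(config.max_classes + 1)
    for K in range(1, config.max_classes + 1):
        spec_k = ModelSpec(
            family=Family.GBTM,
            n_classes=K,
            poly_order_per_class=(preset_poly_order,) * K,
            residual_structure=ResidualStructure.FIXED,
            visit_times=times,
        )
        try:
            fk = _fit(spec_k, enum_seeds[K - 1])
        except (EstimationError, np.linalg.LinAlgError) as exc:
            audit.add(AuditEntry("2:enumeration", _label(spec_k), spec_k,
                                 decision="failed", reason=str(exc)))
            continue
        ok, reason = _admissible(fk, config)
        enum_fits[K] = fk
        enum_admissible[K] = ok
        audit.add(
            AuditEntry(
                stage="2:enumeration", label=_label(spec_k), spec=spec_k,
                **_describe(fk),
                decision="admissible" if ok else "rejected", reason=reason,
            )
        )
        if K > 1 and not ok and config.stop_enumeration_early:
            break

    lrt_rejected: set = set()
    while True:
        cands = [
            enum_fits[K]
            for K in enum_fits
            if enum_admissible[K] and K not in lrt_rejected
        ]
        if not cands:
            stage2_winner = enum_fits[1]
            break
        stage2_winner = _pick_by_bic(cands, config.bic_tie_margin)
        Kw = stage2_winner.spec.n_classes
        if Kw == 1 or (Kw - 1) not in enum_fits:
            break
        lrt = lrt_k_vs_km1(
            data, stage2_winner.spec, enum_fits[Kw - 1].spec,
            config.lrt_replicates, _seed_int(lrt_seeds[Kw]),
            protocol, boot_protocol,
            fitted_k=stage2_winner, fitted_km1=enum_fits[Kw - 1],
        )
        significant = lrt.p_value < config.alpha_lrt
        audit.add(
            AuditEntry(
                stage="2b:lrt", label=_label(stage2_winner.spec),
                spec=stage2_winner.spec, loglik=stage2_winner.loglik,
                lrt_p=lrt.p_value,
                decision="confirmed" if significant else "rejected",
                reason=(
                    f"bootstrap LRT {Kw} vs {Kw - 1}: p={lrt.p_value:.3f}, "
                    f"-2dLL={lrt.observed_stat:.1f}"
                ),
            )
        )
        if significant:
            break
        enum_admissible[Kw] = False
        lrt_rejected.add(Kw)
    K_star = stage2_winner.spec.n_classes

    # ---- stage 3: residual-variance relaxation -----------------------------
    # Enumeration happens under the most constrained model, where unmodeled
    # residual heterogeneity can masquerade as extra classes; with reassess_k
    # the relaxed structures are therefore also fitted at K_star - 1 and the
    # class count re-decided by BIC under the better-specified model.
    candidates3 = [stage2_winner]
    k_options = [K_star]
    if config.reassess_k and K_star > 1:
        k_options.append(K_star - 1)
        if K_star - 1 in enum_fits:
            candidates3.append(enum_fits[K_star - 1])
    specs3 = []
    for K3 in k_options:
        structures = [ResidualStructure.FREE_OVER_TIME]
        if K3 > 1:
            structures += [
                ResidualStructure.FREE_OVER_CLASSES,
                ResidualStructure.FREE_BOTH,
            ]
        specs3 += [
            ModelSpec(
                family=Family.LCGA,
                n_classes=K3,
                poly_order_per_class=(preset_poly_order,) * K3,
                residual_structure=structure,
                visit_times=times,
            )
            for structure in structures
        ]
    resid_seeds = seedseq["resid"].spawn(len(specs3))
    for ss, spec3 in zip(resid_seeds, specs3):
        drop = None
        if spec3.n_classes < K_star:
            drop = int(np.argmin(stage2_winner.params.class_proportions))
        warm = (adapt_parameters(stage2_winner.spec, stage2_winner.params,
                                 spec3, drop_class=drop),)
        try:
            f3 = _screen(spec3, ss, warm)
            if spec3.n_classes == K_star:
                f3 = align_classes(f3, stage2_winner.modal_assignment)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            audit.add(AuditEntry("3:residuals", _label(spec3), spec3,
                                 decision="failed", reason=str(exc)))
            continue
        ok, reason = _admissible(f3, config)
        audit.add(
            AuditEntry(
                stage="3:residuals", label=_label(spec3), spec=spec3,
                **_describe(f3),
                decision="admissible" if ok else "rejected", reason=reason,
            )
        )
        if ok:
            candidates3.append(f3)
    stage3_winner = _pick_by_bic(candidates3, config.bic_tie_margin)
    K_star = stage3_winner.spec.n_classes

    # ---- stage 4: random-effect addition -----------------------------------
    candidates4 = [stage3_winner]
    re_variants = [
        (Family.GMM_CLASS_INVARIANT, ("intercept",)),
        (Family.GMM_CLASS_INVARIANT, ("intercept", "linear_slope")),
        (Family.GMM_CLASS_VARIANT, ("intercept",)),
        (Family.GMM_CLASS_VARIANT, ("intercept", "linear_slope")),
    ]
    if K_star == 1:
        # class-variant == class-invariant for one class
        re_variants = re_variants[:2]
    re_seeds = seedseq["re"].spawn(len(re_variants))
    for ss, (fam, terms) in zip(re_seeds, re_variants):
        spec4 = ModelSpec(
            family=fam,
            n_classes=K_star,
            poly_order_per_class=(preset_poly_order,) * K_star,
            random_effect_terms=terms,
            residual_structure=stage3_winner.spec.residual_structure,
            visit_times=times,
        )
        warm = (adapt_parameters(stage3_winner.spec, stage3_winner.params, spec4),)
        try:
            f4 = align_classes(
                _screen(spec4, ss, warm), stage3_winner.modal_assignment
            )
        except (EstimationError, np.linalg.LinAlgError) as exc:
            audit.add(AuditEntry("4:random_effects", _label(spec4), spec4,
                                 decision="failed", reason=str(exc)))
            continue
        ok, reason = _admissible(f4, config)
        audit.add(
            AuditEntry(
                stage="4:random_effects", label=_label(spec4), spec=spec4,
                **_describe(f4),
                decision="admissible" if ok else "rejected", reason=reason,
            )
        )
        if ok:
            candidates4.append(f4)
    winner = _pick_by_bic(candidates4, config.bic_tie_margin)
    if config.reassess_k and winner.spec.n_classes > 1 and winner is not stage3_winner:
        winner = _confirm_k(
            winner, data, config, protocol, audit,
            np.random.SeedSequence([seed, 41]), "4b:confirm_k",
            fitter=lambda sp, sd, warm: fit(sp, data, protocol, sd, extra_inits=warm),
        )

    # ---- polynomial refinement and normality check -------------------------
    refined = refine_polynomial(
        winner, data, config.alpha_wald, protocol=protocol,
        seed=_seed_int(seedseq["refine"]), audit=audit, screen=True,
    )
    # final model: re-estimated under the full replicated protocol, warm-started
    # from the refined solution
    final = multistart_replicated(
        refined.spec, data, protocol, _seed_int(seedseq["extra"]),
        extra_inits=(refined.params,),
    )
    if final.spec.n_classes == refined.spec.n_classes:
        final = align_classes(final, refined.modal_assignment)
    refined = final
    normality = check_within_class_normality(
        refined, data, min_class_size=config.normality_min_class_size
    )
    refined.fit_indices["normality"] = normality

    audit.mark_selected(_label(refined.spec))
    # ensure the selected model appears in the audit even if unchanged
    if not any(e.selected for e in audit.entries):
        audit.add(
            AuditEntry(
                stage="final", label=_label(refined.spec), spec=refined.spec,
                **_describe(refined), decision="selected", reason="final model",
                selected=True,
            )
        )
    return refined, audit


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# polynomial refinement
# ---------------------------------------------------------------------------


def refine_polynomial(
    fitted: FittedModel,
    data: LongitudinalDataset,
    alpha_wald: float = 0.05,
    protocol: StartProtocol | None = None,
    seed: int = 0,
    audit: SelectionAudit | None = None,
    screen: bool = False,
) -> FittedModel:
    """Iteratively drop the highest non-significant polynomial term.

    Per iteration, each class's top-order coefficient is Wald-tested
    (expected-information standard errors); among the non-significant
    top terms the one with the largest p-value is dropped and the model
    refitted with the class structure re-estimated (labels realigned to
    the previous solution).  Stops when every top term is significant
    or all classes are linear.  A failing refit returns the last valid
    model with an audit note.
    """
    protocol = protocol or StartProtocol()
    current = fitted
    seeds = np.random.SeedSequence([seed, 0x5EF]).spawn(
        sum(fitted.spec.poly_order_per_class)
    )
    step = 0
    while True:
        spec = current.spec
        se = current.se_growth_coefficients
        pvals = []
        for k, order in enumerate(spec.poly_order_per_class):
            if order <= 1:
                continue
            beta_top = current.params.growth_coefficients[k][-1]
            se_top = se[k][-1]
            z = beta_top / se_top if se_top > 0 else np.inf
            p = 2.0 * norm.sf(abs(z))
            if p >= alpha_wald:
                pvals.append((p, k, order))
        if not pvals:
            return current
        pvals.sort(key=lambda t: (-t[0], -t[2]))
        _, k_drop, order = pvals[0]
        new_orders = list(spec.poly_order_per_class)
        new_orders[k_drop] = order - 1
        new_spec = dataclasses.replace(spec, poly_order_per_class=tuple(new_orders))
        warm = (adapt_parameters(spec, current.params, new_spec),)
        try:
            if screen:
                refit = fit(
                    new_spec, data, protocol, _seed_int(seeds[step]),
                    extra_inits=warm,
                )
            else:
                refit = multistart_replicated(
                    new_spec, data, protocol, _seed_int(seeds[step]),
                    extra_inits=warm,
                )
            refit = align_classes(refit, current.modal_assignment)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            if audit is not None:
                audit.add(
                    AuditEntry(
                        "5:refinement", _label(new_spec), new_spec,
                        decision="failed",
                        reason=f"refit failed, keeping previous model: {exc}",
                    )
                )
            return current
        if audit is not None:
            audit.add(
                AuditEntry(
                    stage="5:refinement", label=_label(new_spec), spec=new_spec,
                    **_describe(refit),
                    decision="kept",
                    reason=f"dropped order-{order} term of class {k_drop}",
                )
            )
        current = refit
        step += 1


# ---------------------------------------------------------------------------
# within-class multivariate normality (Mardia)
# ---------------------------------------------------------------------------


def _mardia(X: np.ndarray):
    """Mardia's multivariate skewness and kurtosis statistics with p-values."""
    n, d = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    Sinv = np.linalg.inv(S)
    D = Xc @ Sinv @ Xc.T
    b1 = float((D**3).sum()) / n**2
    b2 = float((np.diag(D) ** 2).mean())
    df = d * (d + 1) * (d + 2) / 6.0
    skew_stat = n * b1 / 6.0
    skew_p = float(chi2.sf(skew_stat, df))
    kurt_z = (b2 - d * (d + 2)) / np.sqrt(8.0 * d * (d + 2) / n)
    kurt_p = float(2.0 * norm.sf(abs(kurt_z)))
    return b1, skew_stat, skew_p, b2, float(kurt_z), kurt_p


def check_within_class_normality(
    fitted: FittedModel,
    data: LongitudinalDataset,
    min_class_size: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mardia skewness/kurtosis test within each modal class.

    Uses complete-case subjects (all scheduled visits observed).  A
    class smaller than ``max(min_class_size, n_visits + 2)`` is marked
    not assessable rather than tested.
    """
    complete = data.mask.all(axis=1)
    T = data.n_visits
    rows = []
    for k in range(fitted.spec.n_classes):
        sel = complete & (fitted.modal_assignment == k)
        nk = int(sel.sum())
        row = {"class": k, "n_complete": nk}
        if nk < max(min_class_size, T + 2):
            row.update(
                assessable=False, flagged=False, skew_stat=np.nan, skew_p=np.nan,
                kurtosis_z=np.nan, kurt_p=np.nan,
            )
        else:
            X = data.y[sel]
            try:
                b1, s_stat, s_p, b2, k_z, k_p = _mardia(X)
            except np.linalg.LinAlgError:
                row.update(
                    assessable=False, flagged=False, skew_stat=np.nan,
                    skew_p=np.nan, kurtosis_z=np.nan, kurt_p=np.nan,
                )
                rows.append(row)
                continue
            row.update(
                assessable=True,
                skew_stat=s_stat, skew_p=s_p,
                kurtosis_z=k_z, kurt_p=k_p,
                flagged=bool(s_p < alpha or k_p < alpha),
            )
        rows.append(row)
    return pd.DataFrame(rows)
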