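"""File I/O, run configuration, and the end-to-end pipeline.

Long-format CSV (``subject_id, time_months, value``) is the native
dialect; a wide-format convenience reader (one column per visit) is
also provided.  :func:`run_pipeline` executes, per outcome, the staged
model selection, endpoint derivation, 3-step covariate and distal
analyses, cross-trajectory risk ratios and the >30%-missing sensitivity
rerun, writing tabular outputs plus a manifest sufficient to reproduce
the run bit-for-bit (config echo, seed, package version).

A single master seed is expanded into fixed per-stage child seeds so
each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import (
    bonferroni_adjust,
    cross_distribution_rr,
    distal_outcome_test,
    membership_proportions,
    misclassification_logits,
    predict_membership,
)
from .endpoints import attrition_filter, derive_endpoints
from .estimation import StartProtocol
from .models import LongitudinalDataset, class_mean_trajectory
from .selection import SelectionConfig, stepwise_select
from .simulate import SyntheticCohort, default_config, generate_cohort

__all__ = [
    "RunConfig",
    "read_long_csv",
    "write_long_csv",
    "read_wide_csv",
    "write_cohort",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("subject_id", "time_months", "value")


def read_long_csv(
    path,
    schedule=None,
    outcome_name: str | None = None,
    value_range=( -np.inf, np.inf),
) -> LongitudinalDataset:
    """Read a long-format outcome CSV into a :class:`LongitudinalDataset`.

    Requires header columns ``subject_id, time_months, value``.  The
    visit schedule defaults to the sorted distinct times in the file;
    passing ``schedule`` makes off-schedule times an error.  Duplicate
    (subject, time) rows and non-numeric values are rejected with their
    row numbers.  Missingness is explicit: a scheduled visit with no
    row (or an empty value) is missing.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing_cols)}")
    for col in ("time_months", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = (bad + 2).tolist()[:5]  # header is line 1
            raise ValueError(f"{path.name}: non-numeric {col} at rows {rows}")
        df[col] = coerced
    dup = df.duplicated(subset=["subject_id", "time_months"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"{path.name}: duplicate (subject, time) rows at {rows}")
    if schedule is None:
        schedule = tuple(sorted(df["time_months"].dropna().unique()))
    else:
        schedule = tuple(float(t) for t in schedule)
        off = ~df["time_months"].isin(schedule)
        if off.any():
            rows = (df.index[off] + 2).tolist()[:5]
            raise ValueError(f"{path.name}: off-schedule times at rows {rows}")
    subjects = df["subject_id"].drop_duplicates().tolist()
    sub_idx = {s: i for i, s in enumerate(subjects)}
    t_idx = {t: j for j, t in enumerate(schedule)}
    y = np.full((len(subjects), len(schedule)), np.nan)
    for sid, t, v in zip(df["subject_id"], df["time_months"], df["value"]):
        if pd.notna(v):
            y[sub_idx[sid], t_idx[float(t)]] = v
    return LongitudinalDataset(
        subject_ids=np.array(subjects, dtype=object),
        visit_times=schedule,
        y=y,
        outcome_name=outcome_name or path.stem,
        value_range=tuple(value_range),
    )


def write_long_csv(dataset: LongitudinalDataset, path) -> Path:
    """Write observed visits of a dataset as long-format CSV (round-trip safe)."""
    path = Path(path)
    rows = []
    mask = dataset.mask
    for i, sid in enumerate(dataset.subject_ids):
        for j, t in enumerate(dataset.visit_times):
            if mask[i, j]:
                rows.append((sid, t, dataset.y[i, j]))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)
    return path


def read_wide_csv(path, outcome_name=None, value_range=(-np.inf, np.inf)):
    """Wide-format reader: ``subject_id`` plus one numeric column per visit time."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path.name}: missing subject_id column")
    time_cols = [c for c in df.columns if c != "subject_id"]
    try:
        times = [float(str(c).lstrip("mt_")) for c in time_cols]
    except ValueError as exc:
        raise ValueError(f"{path.name}: visit columns must encode times: {exc}")
    order = np.argsort(times)
    y = df[time_cols].to_numpy(dtype=float)[:, order]
    return LongitudinalDataset(
        subject_ids=df["subject_id"].to_numpy(dtype=object),
        visit_times=tuple(np.asarray(times)[order]),
        y=y,
        outcome_name=outcome_name or path.stem,
        value_range=tuple(value_range),
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort (outcomes, covariates, truth) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ds in cohort.outcomes.items():
        write_long_csv(ds, out / f"{name}.csv")
    if cohort.covariates is not None:
        cohort.covariates.to_csv(out / "covariates.csv", index=False)
    if cohort.distal is not None:
        cohort.distal.to_csv(out / "distal.csv", index=False)
    if cohort.items:
        for name, tab in cohort.items.items():
            tab.to_csv(out / f"items_{name}.csv", index=False)
    truth = pd.DataFrame({"subject_id": next(iter(cohort.outcomes.values())).subject_ids})
    for name, lab in cohort.true_classes.items():
        truth[f"true_class_{name}"] = lab
    truth.to_csv(out / "true_classes.csv", index=False)
    if cohort.true_endpoints is not None:
        cohort.true_endpoints.to_csv(out / "true_endpoints.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    output_dir: str = "growthmix_run"
    seed: int = 1
    # either generate a synthetic cohort ...
    generate: bool = True
    n_subjects: int = 689
    # ... or read long-format CSVs per outcome
    input_paths: dict = field(default_factory=dict)
    covariate_path: str | None = None
    distal_path: str | None = None
    item_paths: dict = field(default_factory=dict)
    outcomes: list = field(default_factory=list)  # subset to analyze
    preset_orders: dict = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    protocol: StartProtocol = field(
        default_factory=lambda: StartProtocol(n_starts=32, n_final_stage=8)
    )
    sensitivity: bool = True
    max_missing_fraction: float = 0.30
    covariate_columns: list | None = None
    log_transform: list = field(default_factory=list)
    distal_columns: list | None = None
    risk_ratios: bool = True
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "selection" in raw:
            raw["selection"] = SelectionConfig(**raw["selection"])
        if "protocol" in raw:
            raw["protocol"] = StartProtocol(**raw["protocol"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _default_order(n_visits: int) -> int:
    # pre-set order: cubic needs >= 4 visits, quadratic >= 3
    return 3 if n_visits >= 4 else 2


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _trajectory_table(fitted, data) -> pd.DataFrame:
    rows = []
    for k in range(fitted.spec.n_classes):
        mu = class_mean_trajectory(fitted.params, k, data.visit_times)
        row = {"class": k, "n_modal": int(fitted.class_counts[k])}
        row.update({f"m{t:g}": m for t, m in zip(data.visit_times, mu)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full trajectory analysis and write an output tree.

    Per outcome: staged selection -> polynomial refinement -> normality
    check -> endpoint derivation -> fixed-logit covariate and distal
    analyses -> cross-trajectory risk ratios -> optional attrition
    sensitivity rerun.  Returns the output directory.  On a stage
    failure, partial outputs are preserved and the manifest records the
    failure point before the exception propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "growthmix",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": [],
        "status": "running",
    }

    def _save_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "load"
        covariates = distal = None
        items: dict = {}
        cohort = None
        if config.generate:
            gen_cfg = default_config(n_subjects=config.n_subjects, seed=config.seed)
            cohort = generate_cohort(gen_cfg)
            write_cohort(cohort, out / "cohort")
            datasets = dict(cohort.outcomes)
            covariates = cohort.covariates
            distal = cohort.distal
            items = cohort.items or {}
        else:
            datasets = {
                name: read_long_csv(path, outcome_name=name)
                for name, path in config.input_paths.items()
            }
            if config.covariate_path:
                covariates = pd.read_csv(config.covariate_path)
            if config.distal_path:
                distal = pd.read_csv(config.distal_path)
            items = {
                name: pd.read_csv(path) for name, path in config.item_paths.items()
            }
        selected_outcomes = config.outcomes or list(datasets)
        manifest["stages"].append({"stage": stage, "outcomes": selected_outcomes})

        # ---- selection per outcome ---------------------------------------
        fits = {}
        for idx, name in enumerate(selected_outcomes):
            stage = f"select:{name}"
            data = datasets[name]
            order = config.preset_orders.get(name, _default_order(data.n_visits))
            fitted, audit = stepwise_select(
                data,
                preset_poly_order=order,
                config=config.selection,
                seed=config.seed * 1000 + idx,
                protocol=config.protocol,
            )
            fits[name] = fitted
            audit.to_frame().to_csv(out / f"audit_{name}.csv", index=False)
            _trajectory_table(fitted, data).to_csv(
                out / f"trajectories_{name}.csv", index=False
            )
            cls = pd.DataFrame(
                {
                    "subject_id": data.subject_ids,
                    "modal_class": fitted.modal_assignment,
                }
            )
            for k in range(fitted.spec.n_classes):
                cls[f"posterior_{k}"] = fitted.posteriors[:, k]
            cls.to_csv(out / f"classes_{name}.csv", index=False)
            norm_tab = fitted.fit_indices.get("normality")
            if norm_tab is not None:
                norm_tab.to_csv(out / f"normality_{name}.csv", index=False)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "selected": f"{fitted.spec.family.value}/K={fitted.spec.n_classes}",
                    "loglik": fitted.loglik,
                    "bic": fitted.fit_indices["bic"],
                }
            )

        # ---- endpoints ----------------------------------------------------
        stage = "endpoints"
        endpoint_tab = None
        if {"saps", "sans", "sofas"} & set(datasets):
            endpoint_tab = derive_endpoints(
                saps=datasets.get("saps"),
                sans=datasets.get("sans"),
                sofas=datasets.get("sofas"),
                saps_items=items.get("saps"),
                sans_items=items.get("sans"),
            )
            endpoint_tab.to_csv(out / "endpoints.csv", index=False)
            manifest["stages"].append({"stage": stage, "n": len(endpoint_tab)})

        # ---- 3-step covariates & distal outcomes --------------------------
        for name in selected_outcomes:
            stage = f"covariates:{name}"
            fitted = fits[name]
            if fitted.spec.n_classes < 2:
                continue
            logits = misclassification_logits(
                fitted.posteriors, fitted.modal_assignment
            )
            rows = []
            if covariates is not None:
                cov_cols = config.covariate_columns or [
                    c for c in covariates.columns if c != "subject_id"
                ]
                for cname in cov_cols:
                    effects = predict_membership(
                        fitted,
                        logits,
                        covariates[cname].to_numpy(dtype=float),
                        covariate_name=cname,
                        log_transform=cname in config.log_transform,
                    )
                    rows.extend(dataclasses.asdict(e) for e in effects)
            if rows:
                tab = pd.DataFrame(rows)
                thr, flags = bonferroni_adjust(
                    tab["p_value"].to_numpy(), alpha=config.alpha
                )
                tab["bonferroni_threshold"] = thr
                tab["significant"] = flags
                tab.to_csv(out / f"covariates_{name}.csv", index=False)
            drows = []
            if distal is not None:
                d_cols = config.distal_columns or [
                    c for c in distal.columns if c != "subject_id"
                ]
                for dname in d_cols:
                    vals = distal[dname].to_numpy(dtype=float)
                    kind = (
                        "binary"
                        if set(np.unique(vals[np.isfinite(vals)])) <= {0.0, 1.0}
                        else "continuous"
                    )
                    result = distal_outcome_test(
                        fitted, logits, vals, kind, outcome_name=dname
                    )
                    for comp in result.comparisons:
                        row = {"outcome": dname, "kind": kind, **comp}
                        row["pair"] = f"{comp['pair'][0]}v{comp['pair'][1]}"
                        drows.append(row)
            if drows:
                dtab = pd.DataFrame(drows)
                thr, flags = bonferroni_adjust(
                    dtab["p_value"].to_numpy(), alpha=config.alpha
                )
                dtab["bonferroni_threshold"] = thr
                dtab["significant"] = flags
                dtab.to_csv(out / f"distal_{name}.csv", index=False)
            props = membership_proportions(fitted, logits)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "class_distribution_modal": _jsonable(props["modal"]),
                    "step3_proportions": _jsonable(props["posterior_mean"]),
                }
            )

        # ---- cross-trajectory risk ratios ---------------------------------
        stage = "risk_ratios"
        if config.risk_ratios and len(fits) >= 2:
            rr_rows = []
            names = [n for n in selected_outcomes if fits[n].spec.n_classes >= 2]
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    fa, fb = fits[a], fits[b]
                    Ka, Kb = fa.spec.n_classes, fb.spec.n_classes
                    try:
                        rr = cross_distribution_rr(
                            fa.modal_assignment,
                            fb.modal_assignment,
                            target_class_b=Kb - 1,
                            class_a_numerator=Ka - 1,
                            class_a_denominator=0,
                        )
                        rr_rows.append(
                            {
                                "from": a,
                                "to": b,
                                "target_class": Kb - 1,
                                "rr": rr.rr,
                                "ci_low": rr.ci_low,
                                "ci_high": rr.ci_high,
                                "p_value": rr.p_value,
                                "n_excluded": rr.n_excluded,
                            }
                        )
                    except ZeroDivisionError as exc:
                        rr_rows.append({"from": a, "to": b, "error": str(exc)})
            if rr_rows:
                pd.DataFrame(rr_rows).to_csv(out / "risk_ratios.csv", index=False)

        # ---- sensitivity: exclude >30% missing ------------------------------
        if config.sensitivity:
            sens_rows = []
            for idx, name in enumerate(selected_outcomes):
                stage = f"sensitivity:{name}"
                data = datasets[name]
                filtered, excluded = attrition_filter(
                    data, config.max_missing_fraction
                )
                order = config.preset_orders.get(name, _default_order(data.n_visits))
                refit, _ = stepwise_select(
                    filtered,
                    preset_poly_order=order,
                    config=config.selection,
                    seed=config.seed * 1000 + idx,
                    protocol=config.protocol,
                )
                main = fits[name]
                same_spec = refit.spec == dataclasses.replace(
                    main.spec, visit_times=refit.spec.visit_times
                )
                sens_rows.append(
                    {
                        "outcome": name,
                        "n_excluded": len(excluded),
                        "selected_model_identical": bool(same_spec),
                        "main_classes": main.spec.n_classes,
                        "sensitivity_classes": refit.spec.n_classes,
                        "main_proportions": _jsonable(
                            main.fit_indices["class_proportions_modal"]
                        ),
                        "sensitivity_proportions": _jsonable(
                            refit.fit_indices["class_proportions_modal"]
                        ),
                    }
                )
            pd.DataFrame(sens_rows).to_csv(out / "sensitivity.csv", index=False)

        manifest["status"] = "completed"
        _save_manifest()
        return out
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure_point"] = stage
        manifest["error"] = repr(exc)
        _save_manifest()
        raise
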