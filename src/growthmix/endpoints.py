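"""Clinical endpoint derivation from longitudinal score series.

Derives the response/remission/recovery variables used as covariates
and distal outcomes:

* early response: >= 50% reduction in positive, negative, or total
  symptom severity from baseline to month 3;
* symptomatic remission (RSWG-style): all global items <= 2 (attention
  excluded for the negative scale), verified at both scheduled visits
  spanning the final 6-month window (months 18 and 24);
* functional remission: functioning score > 60 (strict) at both months
  12 and 24, i.e. persisting over one year;
* recovery: clinical (positive and negative) plus functional remission.

Endpoints with missing required visits are *not evaluable* (``None`` /
pandas ``NA``), never false-by-default.  Also provides the >30%-missing
attrition filter used for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import LongitudinalDataset

__all__ = [
    "early_response",
    "rswg_symptom_remission",
    "functional_remission",
    "attrition_filter",
    "derive_endpoints",
]


def _value_at(series: pd.Series, time: float):
    if time not in series.index:
        return None
    v = series.loc[time]
    return None if pd.isna(v) else float(v)


def early_response(
    series: pd.Series, baseline_time: float = 0.0, response_time: float = 3.0
) -> bool | None:
    """True when the score at ``response_time`` is <= half the baseline.

    ``series`` is indexed by visit time (months).  Returns ``None``
    (not evaluable) when either visit is unobserved.  A zero baseline is
    degenerate: response then means staying at zero.
    """
    base = _value_at(series, baseline_time)
    resp = _value_at(series, response_time)
    if base is None or resp is None:
        return None
    if base == 0:
        return resp == 0
    return resp <= 0.5 * base


def rswg_symptom_remission(
    items_by_time: dict,
    check_times: tuple[float, float] = (18.0, 24.0),
    threshold: float = 2.0,
    exclude_item: int | None = None,
) -> bool | None:
    """Symptom remission sustained over the final window.

    ``items_by_time`` maps visit time to the vector of global item
    scores.  Remission requires every item (optionally excluding one,
    e.g. the attention item of the negative scale) to be at or below
    ``threshold`` at *both* check times — the two scheduled visits
    bounding the 6-month window.  Missing either visit makes the
    endpoint not evaluable.
    """
    checks = []
    for t in check_times:
        items = items_by_time.get(t)
        if items is None:
            return None
        items = np.asarray(items, dtype=float)
        if np.any(np.isnan(items)):
            return None
        if exclude_item is not None:
            items = np.delete(items, exclude_item)
        checks.append(bool(np.all(items <= threshold)))
    return all(checks)


def functional_remission(
    sofas_series: pd.Series,
    check_times: tuple[float, float] = (12.0, 24.0),
    cutoff: float = 60.0,
) -> bool | None:
    """Good functioning (score strictly above ``cutoff``) at both check times."""
    vals = [_value_at(sofas_series, t) for t in check_times]
    if any(v is None for v in vals):
        return None
    return all(v > cutoff for v in vals)


def attrition_filter(
    dataset: LongitudinalDataset, max_missing_fraction: float = 0.30
):
    """Exclude subjects missing more than ``max_missing_fraction`` of visits.

    Returns ``(filtered_dataset, report)`` where the report lists every
    excluded subject with its missing fraction.
    """
    frac = dataset.missing_fraction()
    keep = frac <= max_missing_fraction
    report = pd.DataFrame(
        {
            "subject_id": dataset.subject_ids[~keep],
            "missing_fraction": frac[~keep],
        }
    )
    return dataset.subset(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# cohort-level derivation
# ---------------------------------------------------------------------------


def _series(ds: LongitudinalDataset, i: int) -> pd.Series:
    return pd.Series(ds.y[i], index=list(ds.visit_times))


def _items_map(items: pd.DataFrame | None, sid) -> dict:
    """Per-visit item vectors for one subject from a long item table."""
    if items is None:
        return {}
    sub = items[items["subject_id"] == sid]
    out = {}
    for t, grp in sub.groupby("time_months"):
        vec = grp.sort_values("item")["value"].to_numpy(dtype=float)
        out[float(t)] = vec
    return out


def derive_endpoints(
    saps: LongitudinalDataset | None = None,
    sans: LongitudinalDataset | None = None,
    sofas: LongitudinalDataset | None = None,
    saps_items: pd.DataFrame | None = None,
    sans_items: pd.DataFrame | None = None,
    attention_item: int = -1,
    total_mode: str = "sum",
) -> pd.DataFrame:
    """Per-subject endpoint flags for a cohort.

    Item tables are long format (``subject_id, time_months, item,
    value``); ``attention_item`` indexes the item excluded from
    negative-symptom remission (default: the last).  ``total_mode``
    controls the early response on total symptoms: ``"sum"`` thresholds
    the summed series (both components observed per visit), ``"both"``
    requires early response on each scale separately.

    Output uses pandas nullable booleans, ``NA`` = not evaluable, and
    carries degenerate-baseline flags for the early-response endpoints.
    Logical structure: ``clinical_remission = remission_pos &
    remission_neg``; ``recovery = clinical_remission &
    functional_remission``.
    """
    datasets = [d for d in (saps, sans, sofas) if d is not None]
    if not datasets:
        raise ValueError("at least one outcome dataset is required")
    ids = datasets[0].subject_ids
    for d in datasets[1:]:
        if not np.array_equal(d.subject_ids, ids):
            raise ValueError("all datasets must share the same subjects in order")

    n = ids.size
    cols: dict[str, list] = {}

    def _add(name, values):
        cols[name] = values

    def _na_and(x, y):
        if x is None or y is None:
            return None
        return x and y

    er_pos, er_neg, er_tot = [None] * n, [None] * n, [None] * n
    deg_pos, deg_neg = [False] * n, [False] * n
    rem_pos, rem_neg, func_rem = [None] * n, [None] * n, [None] * n

    if sans_items is not None:
        n_sans_items = int(sans_items["item"].max()) + 1
        att = attention_item % n_sans_items
    for i, sid in enumerate(ids):
        if saps is not None:
            s = _series(saps, i)
            er_pos[i] = early_response(s)
            b = _value_at(s, 0.0)
            deg_pos[i] = b == 0
        if sans is not None:
            s = _series(sans, i)
            er_neg[i] = early_response(s)
            b = _value_at(s, 0.0)
            deg_neg[i] = b == 0
        if saps is not None and sans is not None:
            if total_mode == "both":
                er_tot[i] = _na_and(er_pos[i], er_neg[i])
            else:
                sa, sn = _series(saps, i), _series(sans, i)
                ok = sa.notna() & sn.notna()
                tot = (sa + sn)[ok]
                er_tot[i] = early_response(tot)
        if saps_items is not None:
            er = rswg_symptom_remission(_items_map(saps_items, sid))
            rem_pos[i] = er
        if sans_items is not None:
            rem_neg[i] = rswg_symptom_remission(
                _items_map(sans_items, sid), exclude_item=att
            )
        if sofas is not None:
            func_rem[i] = functional_remission(_series(sofas, i))

    clin = [_na_and(p, q) for p, q in zip(rem_pos, rem_neg)]
    rec = [_na_and(c, f) for c, f in zip(clin, func_rem)]

    _add("subject_id", list(ids))
    if saps is not None:
        _add("early_response_pos", er_pos)
        _add("early_response_pos_degenerate", deg_pos)
    if sans is not None:
        _add("early_response_neg", er_neg)
        _add("early_response_neg_degenerate", deg_neg)
    if saps is not None and sans is not None:
        _add("early_response_total", er_tot)
    if saps_items is not None:
        _add("remission_pos", rem_pos)
    if sans_items is not None:
        _add("remission_neg", rem_neg)
    if saps_items is not None and sans_items is not None:
        _add("clinical_remission", clin)
    if sofas is not None:
        _add("functional_remission", func_rem)
    if saps_items is not None and sans_items is not None and sofas is not None:
        _add("recovery", rec)

    out = pd.DataFrame(cols)
    for c in out.columns:
        if c == "subject_id" or c.endswith("_degenerate"):
            continue
        out[c] = pd.array(out[c], dtype="boolean")
    return out
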