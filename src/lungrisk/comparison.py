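"""Count-matched comparison of risk models against screening criteria.

For each criterion the models are thresholded so that they select exactly
as many subjects as the criterion does; performance is then compared by
sensitivity/specificity and the number of incident cases captured at each
model's native horizon.

Tie policy: the threshold is the n-th largest risk; if several subjects
share the threshold risk, the tied subjects with the smallest ids are kept
so the selection size matches the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .criteria import evaluate_criteria
from .engines import score_cohort
from .errors import DataError, UndefinedMetricError
from .validation import outcomes_at_horizon

__all__ = ["match_threshold", "confusion_metrics", "compare_all", "ScreeningComparison"]

HORIZONS = [5.0, 6.0, 6.6, 8.7, 10.0]


@dataclass
class ScreeningComparison:
    criteria: str
    model: str
    n_selected_by_criteria: int
    threshold: float
    n_selected_by_model: int
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    horizon: float
    cases_selected: int
    cases_total: int


def match_threshold(risks, n_target: int, ids=None) -> tuple[float, set]:
    """Pick the ``n_target`` highest-risk subjects.

    Returns (threshold, selected id set) where the threshold is the
    n_target-th largest risk.  Ties at the threshold beyond the target
    count are resolved by keeping the tied subjects with the smallest ids.
    """
    risks = np.asarray(risks, dtype=float)
    n = len(risks)
    if not (0 < n_target <= n):
        raise DataError(f"n_target {n_target} out of range (1..{n})")
    if ids is None:
        ids = np.array([str(i) for i in range(n)], dtype=object)
    else:
        ids = np.asarray(ids, dtype=object)
    threshold = float(np.sort(risks)[n - n_target])
    above = risks > threshold
    n_above = int(above.sum())
    tied = np.flatnonzero(risks == threshold)
    need = n_target - n_above
    tied_sorted = tied[np.argsort(ids[tied].astype(str), kind="stable")]
    selected = set(ids[above]) | set(ids[tied_sorted[:need]])
    assert len(selected) == n_target
    return threshold, selected


def confusion_metrics(selected_ids, ids, outcomes) -> dict:
    """TP/FN/FP/TN and sensitivity/specificity for a selected set."""
    ids = np.asarray(ids, dtype=object)
    y = np.asarray(outcomes, dtype=bool)
    sel = np.isin(ids, list(selected_ids))
    if len(set(selected_ids) - set(ids)) > 0:
        raise DataError("selected ids not all in cohort")
    tp = int((sel & y).sum())
    fn = int((~sel & y).sum())
    fp = int((sel & ~y).sum())
    tn = int((~sel & ~y).sum())
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: zero cases")
    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp) if tn + fp > 0 else float("nan"),
    }


def compare_all(cohort: Cohort, criteria_name: str, specs,
                censor_policy: str = "include", **criteria_kwargs) -> pd.DataFrame:
    """Criteria-vs-models table for one cohort panel.

    Ever-only models are skipped when the cohort contains never smokers
    (they appear only in ever-smoker panels).  Each model row reports the
    matched threshold, sensitivity/specificity and cases captured at the
    model's native horizon; the criteria row reports cases captured at
    every horizon.
    """
    elig = evaluate_criteria(cohort, criteria_name, **criteria_kwargs)
    mask = elig["eligible"].to_numpy()
    n_target = int(mask.sum())
    if n_target == 0:
        raise DataError(f"criteria {criteria_name!r} selected no subjects")
    ids = cohort.df["id"].to_numpy(dtype=object)
    selected_by_criteria = set(ids[mask])
    has_never = (cohort.df["smoking_status"] == "never").any()

    rows = []
    for h in HORIZONS:
        y, _ = outcomes_at_horizon(cohort, h, censor_policy="include")
        cases_total = int(y.sum())
        if cases_total == 0:
            continue
        met = confusion_metrics(selected_by_criteria, ids, y)
        rows.append({
            "criteria": criteria_name, "model": None, "horizon": h,
            "threshold": np.nan, "n_selected": n_target,
            "cases_selected": met["tp"], "cases_total": cases_total,
            "sensitivity": met["sensitivity"], "specificity": met["specificity"],
            **{k: met[k] for k in ("tp", "fn", "fp", "tn")},
        })

    for spec in specs:
        if spec.population == "ever_only" and has_never:
            continue
        scored = score_cohort(spec, cohort, on_population="error")
        threshold, selected = match_threshold(scored["risk"].to_numpy(), n_target,
                                              ids=scored["id"].to_numpy(dtype=object))
        h = float(spec.horizon)
        y, _ = outcomes_at_horizon(cohort, h, censor_policy="include")
        met = confusion_metrics(selected, ids, y)
        rows.append({
            "criteria": criteria_name, "model": spec.name, "horizon": h,
            "threshold": threshold, "n_selected": len(selected),
            "cases_selected": met["tp"], "cases_total": int(y.sum()),
            "sensitivity": met["sensitivity"], "specificity": met["specificity"],
            **{k: met[k] for k in ("tp", "fn", "fp", "tn")},
        })
    return pd.DataFrame(rows)
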