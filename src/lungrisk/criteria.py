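"""Screening eligibility rules: T/CPMA 013-2020, USPSTF-2021, NELSON.

Boundary inclusivity follows the printed criteria symbols exactly
(>=, >, <, <=).  Two T/CPMA clauses have no directly collected predictor
and are operationalised by explicit, swappable proxies:

* clause (c), long-term passive smoking: daily secondhand-smoke hours at
  or above a configurable threshold (default 1 hour/day);
* clause (e), occupational carcinogen exposure: the asbestos-exposure
  flag (the only occupational-exposure field collected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectRecord
from .errors import EligibilityError

__all__ = [
    "EligibilityResult",
    "eligible_uspstf",
    "eligible_nelson",
    "eligible_tcpma",
    "evaluate_criteria",
    "CRITERIA_NAMES",
]

CRITERIA_NAMES = ["tcpma", "uspstf", "nelson"]


@dataclass
class EligibilityResult:
    subject_id: str
    criteria: str
    eligible: bool
    triggered_clauses: list[str] = field(default_factory=list)


def _req(subject: SubjectRecord, name: str, criteria: str):
    v = subject.get(name)
    if v is None:
        raise EligibilityError(
            f"{criteria}: required field {name!r} missing for subject {subject.id}")
    return v


def _smoker_fields(subject: SubjectRecord, criteria: str, names: list[str]) -> dict:
    status = _req(subject, "smoking_status", criteria)
    if status == "never":
        return {"smoking_status": status}
    out = {"smoking_status": status}
    for n in names:
        out[n] = _req(subject, n, criteria)
    return out


def eligible_uspstf(subject: SubjectRecord) -> EligibilityResult:
    """Age 50-80, current or former smoker who quit <= 15 years, >= 20 pack-years."""
    age = _req(subject, "age", "uspstf")
    f = _smoker_fields(subject, "uspstf", ["quit_years", "pack_years"])
    clauses = []
    if 50 <= age <= 80:
        clauses.append("age")
    if f["smoking_status"] in ("current", "former") and f.get("quit_years", np.inf) <= 15:
        clauses.append("smoking")
    if f.get("pack_years", 0) >= 20:
        clauses.append("pack_years")
    ok = {"age", "smoking", "pack_years"} <= set(clauses)
    return EligibilityResult(subject.id, "uspstf", ok, clauses if ok else [])


def eligible_nelson(subject: SubjectRecord) -> EligibilityResult:
    """Age 50-74, quit <= 10 years, and (> 15 cpd for > 25 years) or
    (> 10 cpd for > 30 years); intensity/duration inequalities strict."""
    age = _req(subject, "age", "nelson")
    f = _smoker_fields(subject, "nelson", ["quit_years", "cigarettes_per_day", "smoking_years"])
    clauses = []
    if 50 <= age <= 74:
        clauses.append("age")
    if f["smoking_status"] in ("current", "former") and f.get("quit_years", np.inf) <= 10:
        clauses.append("smoking")
    cpd = f.get("cigarettes_per_day", 0)
    yrs = f.get("smoking_years", 0)
    if cpd > 15 and yrs > 25:
        clauses.append("heavy")
    if cpd > 10 and yrs > 30:
        clauses.append("long")
    ok = "age" in clauses and "smoking" in clauses and ("heavy" in clauses or "long" in clauses)
    return EligibilityResult(subject.id, "nelson", ok, clauses if ok else [])


def eligible_tcpma(subject: SubjectRecord,
                   passive_smoke_hours_threshold: float = 1.0) -> EligibilityResult:
    """Age 50-74 (mandatory) plus at least one of clauses (b)-(f).

    (b) >= 30 pack-years, current or former who quit < 15 years;
    (c) passive-smoking proxy (secondhand hours/day >= threshold);
    (d) COPD history; (e) occupational carcinogen proxy (asbestos);
    (f) first-degree family history of lung cancer.
    """
    age = _req(subject, "age", "tcpma")
    clauses = []
    if not (50 <= age <= 74):
        return EligibilityResult(subject.id, "tcpma", False, [])
    clauses.append("a")

    status = _req(subject, "smoking_status", "tcpma")
    if status in ("current", "former"):
        py = _req(subject, "pack_years", "tcpma")
        qy = _req(subject, "quit_years", "tcpma")
        if py >= 30 and (status == "current" or qy < 15):
            clauses.append("b")
    shs = _req(subject, "secondhand_smoke_hours_per_day", "tcpma")
    if shs >= passive_smoke_hours_threshold:
        clauses.append("c")
    if _req(subject, "copd", "tcpma"):
        clauses.append("d")
    if _req(subject, "asbestos_exposure", "tcpma"):
        clauses.append("e")
    if _req(subject, "family_history_lc", "tcpma") == "first_degree":
        clauses.append("f")
    ok = len(clauses) > 1  # "a" plus at least one of b-f
    return EligibilityResult(subject.id, "tcpma", ok, clauses if ok else [])


_VECTOR_IMPL = {}


def _vec_uspstf(df: pd.DataFrame) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    smoker = df["smoking_status"].isin(["current", "former"]).to_numpy()
    quit = df["quit_years"].to_numpy(dtype=float)
    py = df["pack_years"].to_numpy(dtype=float)
    return ((age >= 50) & (age <= 80) & smoker
            & (np.nan_to_num(quit, nan=np.inf) <= 15)
            & (np.nan_to_num(py) >= 20))


def _vec_nelson(df: pd.DataFrame) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    smoker = df["smoking_status"].isin(["current", "former"]).to_numpy()
    quit = np.nan_to_num(df["quit_years"].to_numpy(dtype=float), nan=np.inf)
    cpd = np.nan_to_num(df["cigarettes_per_day"].to_numpy(dtype=float))
    yrs = np.nan_to_num(df["smoking_years"].to_numpy(dtype=float))
    return ((age >= 50) & (age <= 74) & smoker & (quit <= 10)
            & (((cpd > 15) & (yrs > 25)) | ((cpd > 10) & (yrs > 30))))


def _vec_tcpma(df: pd.DataFrame, passive_smoke_hours_threshold: float = 1.0) -> np.ndarray:
    age = df["age"].to_numpy(dtype=float)
    gate = (age >= 50) & (age <= 74)
    status = df["smoking_status"]
    py = np.nan_to_num(df["pack_years"].to_numpy(dtype=float))
    qy = np.nan_to_num(df["quit_years"].to_numpy(dtype=float), nan=np.inf)
    b = (py >= 30) & ((status == "current").to_numpy()
                      | ((status == "former").to_numpy() & (qy < 15)))
    c = df["secondhand_smoke_hours_per_day"].to_numpy(dtype=float) >= passive_smoke_hours_threshold
    d = df["copd"].fillna(False).to_numpy(dtype=bool)
    e = df["asbestos_exposure"].fillna(False).to_numpy(dtype=bool)
    f = (df["family_history_lc"] == "first_degree").to_numpy()
    return gate & (b | c | d | e | f)


_VECTOR_IMPL.update({"uspstf": _vec_uspstf, "nelson": _vec_nelson, "tcpma": _vec_tcpma})


def evaluate_criteria(cohort: Cohort, name: str, **kwargs) -> pd.DataFrame:
    """Vectorized criteria evaluation: DataFrame with id and eligible columns.

    Missing values are treated conservatively (a missing disqualifying
    field fails its clause); use the per-subject functions for strict
    missing-field errors.
    """
    name = name.lower()
    if name not in _VECTOR_IMPL:
        raise EligibilityError(f"unknown criteria {name!r}; known: {CRITERIA_NAMES}")
    mask = _VECTOR_IMPL[name](cohort.df, **kwargs)
    return pd.DataFrame({"id": cohort.df["id"].to_numpy(),
                         "criteria": name, "eligible": mask})
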