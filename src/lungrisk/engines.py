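"""Absolute-risk engines: evaluate a ModelSpec on subjects.

Four mathematical forms are supported:

``logistic_direct``
    risk = expit(intercept + sum of terms).
``cox_baseline``
    risk = 1 - S0(horizon) ** exp(lp - lp_center).
``rr_times_incidence``
    relative risk exp(lp) applied on the odds scale to an age/sex
    baseline absolute risk.
``annual_recursion``
    yearly lung-cancer hazard (scaled by exp(lp - lp_center)) competing
    with yearly other-cause mortality, accumulated over the horizon;
    a fractional final year contributes a pro-rata hazard fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, SMOKER_ONLY_COLUMNS, SubjectRecord
from .errors import EvaluationError, PopulationError, SpecError
from .registry import ModelSpec, Term

__all__ = [
    "RiskPrediction",
    "evaluate_linear_predictor",
    "risk_logistic",
    "risk_cox",
    "risk_rr_incidence",
    "risk_annual_recursion",
    "predict",
    "score_cohort",
]

_SMOKER_ONLY = set(SMOKER_ONLY_COLUMNS)


@dataclass
class RiskPrediction:
    subject_id: str
    model: str
    horizon: float
    risk: float
    linear_predictor: float


# ---------------------------------------------------------------------------
# term evaluation

def _term_values(term: Term, df: pd.DataFrame, never: np.ndarray) -> np.ndarray:
    """Transformed values (pre-coefficient) of one term, vectorized."""
    tr = term.transform
    ttype = tr["type"]
    col = df[term.field]

    if ttype in ("categorical",):
        s = col.astype(object)
        mapped = s.map({str(k): float(v) for k, v in tr["mapping"].items()})
        bad = s.notna() & mapped.isna()
        if bad.any():
            val = s[bad].iloc[0]
            raise EvaluationError(
                f"unmapped level {val!r} for field {term.field!r} "
                f"(subject {df['id'][bad].iloc[0]})")
        if mapped.isna().any():
            rid = df["id"][mapped.isna()].iloc[0]
            raise EvaluationError(f"missing predictor {term.field!r} (subject {rid})")
        return mapped.to_numpy(dtype=float) - float(tr.get("center", 0.0))

    if ttype == "indicator":
        x = col.astype("boolean")
        if term.never_raw is not None and never.any():
            x = x.where(~never, bool(term.never_raw))
        if x.isna().any():
            rid = df["id"][x.isna()].iloc[0]
            raise EvaluationError(f"missing predictor {term.field!r} (subject {rid})")
        return x.to_numpy(dtype=float)

    # numeric transforms
    x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if term.never_raw is not None and never.any():
        x = np.where(never, float(term.never_raw), x)
    if np.isnan(x).any():
        rid = df["id"][np.isnan(x)].iloc[0]
        raise EvaluationError(f"missing predictor {term.field!r} (subject {rid})")
    if term.truncate is not None:
        lo, hi = term.truncate
        x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)

    if ttype == "identity":
        return x
    if ttype == "center":
        return x - float(tr["value"])
    if ttype == "log":
        arg = x + float(tr.get("offset", 0.0))
        if np.any(arg <= 0):
            raise EvaluationError(f"log transform of non-positive value for {term.field!r}")
        return np.log(arg) - float(tr.get("center", 0.0))
    if ttype == "power":
        base = x / float(tr.get("scale", 1.0))
        return np.power(base, float(tr["exponent"])) - float(tr.get("center", 0.0))
    if ttype == "bin":
        idx = np.searchsorted(np.asarray(tr["breaks"], dtype=float), x, side="right")
        return np.asarray(tr["values"], dtype=float)[idx]
    raise SpecError(f"unknown transform type {ttype!r}")  # pragma: no cover


def _check_population(spec: ModelSpec, df: pd.DataFrame) -> np.ndarray:
    status = df["smoking_status"]
    never = (status == "never").to_numpy()
    if spec.population == "ever_only" and never.any():
        rid = df["id"][never].iloc[0]
        raise PopulationError(
            f"model {spec.name} is restricted to ever smokers (subject {rid} is a never smoker)")
    if status.isna().any():
        rid = df["id"][status.isna()].iloc[0]
        raise EvaluationError(f"missing predictor 'smoking_status' (subject {rid})")
    return never


def _lp_frame(spec: ModelSpec, df: pd.DataFrame) -> np.ndarray:
    never = _check_population(spec, df)
    lp = np.full(len(df), float(spec.intercept))
    for term in spec.terms:
        smoker_only = term.field in _SMOKER_ONLY
        if smoker_only and never.any() and term.never_raw is None and term.ttype != "categorical":
            rid = df["id"][never].iloc[0]
            raise EvaluationError(
                f"term on smoker-only field {term.field!r} has no never_raw "
                f"but cohort contains never smokers (subject {rid})")
        lp += term.coef * _term_values(term, df, never)
    return lp


# ---------------------------------------------------------------------------
# elementary risk forms (spec-level operations)

def risk_logistic(lp):
    """Logistic link: 1 / (1 + exp(-lp))."""
    return expit(lp)


def risk_cox(lp, s0):
    """Cox absolute risk 1 - s0 ** exp(lp); requires 0 < s0 <= 1."""
    s0 = float(s0)
    if not (0.0 < s0 <= 1.0):
        raise SpecError(f"baseline survival s0={s0} outside (0, 1]")
    return 1.0 - s0 ** np.exp(lp)


def risk_rr_incidence(rr, baseline_risk):
    """Apply a relative risk to a baseline risk on the odds scale, cap at 1."""
    rr = np.asarray(rr, dtype=float)
    base = np.asarray(baseline_risk, dtype=float)
    if np.any(rr < 0):
        raise SpecError("relative risk must be non-negative")
    if np.any((base < 0) | (base >= 1)):
        raise SpecError("baseline risk must lie in [0, 1)")
    odds = base / (1.0 - base) * rr
    out = np.clip(odds / (1.0 + odds), 0.0, 1.0)
    return out if out.ndim else float(out)


def risk_annual_recursion(annual_lc_hazard, annual_mort_hazard, horizon):
    """Cumulative probability of the event over ``horizon`` years.

    ``annual_lc_hazard[k]`` / ``annual_mort_hazard[k]`` are the hazards in
    year k+1.  Tables may be 1-D (one subject) or 2-D (subjects x years).
    A fractional final year contributes ``surv * h_lc * frac``.
    """
    h_lc = np.atleast_2d(np.asarray(annual_lc_hazard, dtype=float))
    h_m = np.atleast_2d(np.asarray(annual_mort_hazard, dtype=float))
    if np.any((h_lc < 0) | (h_lc > 1)) or np.any((h_m < 0) | (h_m > 1)):
        raise SpecError("annual hazards must lie in [0, 1]")
    if h_lc.shape != h_m.shape:
        raise SpecError("hazard tables must have equal shape")
    horizon = float(horizon)
    if horizon <= 0:
        raise SpecError("horizon must be positive")
    full = int(math.floor(horizon))
    frac = horizon - full
    needed = full + (1 if frac > 0 else 0)
    if h_lc.shape[1] < needed:
        raise SpecError(f"hazard tables cover {h_lc.shape[1]} years; horizon needs {needed}")
    surv = np.ones(h_lc.shape[0])
    risk = np.zeros(h_lc.shape[0])
    for k in range(full):
        risk += surv * h_lc[:, k]
        surv *= (1.0 - h_lc[:, k]) * (1.0 - h_m[:, k])
    if frac > 0:
        risk += surv * h_lc[:, full] * frac
    risk = np.clip(risk, 0.0, 1.0)
    return risk if np.ndim(annual_lc_hazard) > 1 else float(risk[0])


# ---------------------------------------------------------------------------
# spec dispatch

def _age_sex_lookup(table: dict, ages: np.ndarray, is_male: np.ndarray) -> np.ndarray:
    breaks = np.asarray(table["age_breaks"], dtype=float)
    male = np.asarray(table["male"], dtype=float)
    female = np.asarray(table["female"], dtype=float)
    idx = np.searchsorted(breaks, ages, side="right")
    return np.where(is_male, male[idx], female[idx])


def _risk_frame(spec: ModelSpec, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    lp = _lp_frame(spec, df)
    if spec.form == "logistic_direct":
        return risk_logistic(lp), lp

    if spec.form == "cox_baseline":
        lpc = float(spec.baselines.get("lp_center", 0.0))
        return risk_cox(lp - lpc, spec.baselines["s0"]), lp

    age = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(age).any():
        rid = df["id"][np.isnan(age)].iloc[0]
        raise EvaluationError(f"missing predictor 'age' (subject {rid})")
    sex = df["sex"]
    if sex.isna().any():
        rid = df["id"][sex.isna()].iloc[0]
        raise EvaluationError(f"missing predictor 'sex' (subject {rid})")
    is_male = (sex == "male").to_numpy()

    if spec.form == "rr_times_incidence":
        base = _age_sex_lookup(spec.baselines["baseline_risk"], age, is_male)
        return np.asarray(risk_rr_incidence(np.exp(lp), base)), lp

    if spec.form == "annual_recursion":
        lpc = float(spec.baselines.get("lp_center", 0.0))
        hr = np.exp(lp - lpc)
        years = int(math.ceil(spec.horizon))
        h_lc = np.empty((len(df), years))
        h_m = np.empty((len(df), years))
        for k in range(years):
            h_lc[:, k] = _age_sex_lookup(spec.baselines["annual_lc_hazard"], age + k, is_male)
            h_m[:, k] = _age_sex_lookup(spec.baselines["annual_mort_hazard"], age + k, is_male)
        h_lc = np.clip(h_lc * hr[:, None], 0.0, 0.999)
        return risk_annual_recursion(h_lc, h_m, spec.horizon), lp

    raise SpecError(f"unknown form {spec.form!r}")  # pragma: no cover


def _subject_frame(subject: SubjectRecord) -> pd.DataFrame:
    d = {k: (np.nan if v is None else v) for k, v in vars(subject).items()}
    return pd.DataFrame([d])


def evaluate_linear_predictor(spec: ModelSpec, subject: SubjectRecord) -> float:
    """intercept + sum(coef x transformed predictor) for one subject."""
    return float(_lp_frame(spec, _subject_frame(subject))[0])


def predict(spec: ModelSpec, subject: SubjectRecord) -> RiskPrediction:
    """Absolute risk of one subject over the model's horizon."""
    risk, lp = _risk_frame(spec, _subject_frame(subject))
    return RiskPrediction(subject_id=subject.id, model=spec.name,
                          horizon=spec.horizon, risk=float(risk[0]),
                          linear_predictor=float(lp[0]))


def score_cohort(spec: ModelSpec, cohort, on_population: str = "error") -> pd.DataFrame:
    """Score every subject; returns id, model, horizon, risk, linear_predictor.

    ``on_population="subset"`` silently restricts an ever-only model to the
    ever smokers instead of raising.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if on_population == "subset" and spec.population == "ever_only":
        df = df[df["smoking_status"].isin(["current", "former"])].reset_index(drop=True)
    risk, lp = _risk_frame(spec, df)
    if np.any((risk < 0) | (risk > 1) | ~np.isfinite(risk)):
        raise EvaluationError(f"model {spec.name} produced risks outside [0, 1]")
    return pd.DataFrame({
        "id": df["id"].to_numpy(),
        "model": spec.name,
        "horizon": spec.horizon,
        "risk": risk,
        "linear_predictor": lp,
    })
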