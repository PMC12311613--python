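"""Discrimination, calibration, multiple imputation and pooling.

Conventions
-----------
* The "E/O ratio" is expected / observed: the sum of predicted risks
  divided by the observed case count.  Values below 1 mean the model
  underestimates risk relative to observed incidence.
* Outcome at horizon t: a subject is a case iff event and time <= t;
  subjects censored before t without an event count as controls by
  default (``censor_policy="include"``) or can be excluded.
* AUC confidence intervals use the DeLong variance; E/O intervals use a
  Poisson approximation on the observed count, ratio * exp(-+ z / sqrt(O)).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.linear_model import LinearRegression, LogisticRegression

from .cohort import Cohort, SMOKER_ONLY_COLUMNS
from .errors import DataError, ImputationError, UndefinedMetricError

__all__ = [
    "auc",
    "auc_delong_variance",
    "auc_ci",
    "eo_ratio",
    "calibration_bins",
    "mice_impute",
    "rubin_pool",
    "PooledEstimate",
    "ValidationReport",
    "outcomes_at_horizon",
    "validate_model",
    "radial_feature_summary",
]


def _split_scores(scores, outcomes):
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if not y.any():
        raise UndefinedMetricError("AUC undefined: no cases")
    if y.all():
        raise UndefinedMetricError("AUC undefined: no controls")
    return scores, y


def auc(scores, outcomes) -> float:
    """Mann-Whitney concordance: P(random case outscores random control),
    ties counted 1/2."""
    scores, y = _split_scores(scores, outcomes)
    r = rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_delong_variance(scores, outcomes) -> tuple[float, float]:
    """(AUC, DeLong variance) via placement values."""
    scores, y = _split_scores(scores, outcomes)
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v01 = (r_all[:m] - r_pos) / n          # placements of cases among controls
    v10 = 1.0 - (r_all[m:] - r_neg) / m    # placements of controls among cases
    a = float(v01.mean())
    s01 = float(v01.var(ddof=1)) if m > 1 else 0.0
    s10 = float(v10.var(ddof=1)) if n > 1 else 0.0
    return a, s01 / m + s10 / n


def auc_ci(scores, outcomes, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation interval, clipped to [0, 1]."""
    a, var = auc_delong_variance(scores, outcomes)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(np.clip(a - half, 0.0, 1.0)), float(np.clip(a + half, 0.0, 1.0)))


def eo_ratio(predicted, outcomes, level: float = 0.95) -> dict:
    """Expected/observed ratio with a Poisson log-scale interval on O."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("predicted and outcomes must have equal length")
    O = int(y.sum())
    if O == 0:
        raise UndefinedMetricError("E/O undefined: zero observed cases")
    E = float(p.sum())
    ratio = E / O
    z = norm.ppf(0.5 + level / 2.0)
    return {
        "expected": E,
        "observed": O,
        "eo_ratio": ratio,
        "eo_ci": (ratio * float(np.exp(-z / np.sqrt(O))),
                  ratio * float(np.exp(z / np.sqrt(O)))),
    }


def calibration_bins(predicted, outcomes, n_bins: int = 4) -> pd.DataFrame:
    """Quantile calibration groups by ascending predicted risk.

    Subjects are stable-sorted by predicted risk (ties keep input order)
    and split into ``n_bins`` nearly equal groups; earlier groups take the
    remainder (sizes from ``numpy.array_split``, e.g. 10 -> 3,3,2,2).
    The last bin is the "high risk" group.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if len(p) < n_bins:
        raise DataError(f"need at least {n_bins} subjects, got {len(p)}")
    order = np.argsort(p, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        rows.append({
            "bin": b + 1,
            "n": len(idx),
            "mean_predicted": float(p[idx].mean()),
            "observed_proportion": float(y[idx].mean()),
            "cases": int(y[idx].sum()),
            "high_risk": b == n_bins - 1,
        })
    return pd.DataFrame(rows)


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate over m imputations."""

    point: float
    within_variance: float
    between_variance: float
    total_variance: float
    m: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(self.total_variance)
        return (self.point - half, self.point + half)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """point = mean, W = mean variance, B = sample variance of estimates,
    T = W + (1 + 1/m) B."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(est)
    if m < 2:
        raise DataError("Rubin pooling requires m >= 2 imputations")
    point = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    return PooledEstimate(point, W, B, W + (1 + 1 / m) * B, m)


# ---------------------------------------------------------------------------
# multiple imputation by chained equations

_CONTINUOUS_IMPUTABLE = ["bmi", "height", "smoking_years", "quit_years", "cigarettes_per_day"]
_CATEGORICAL_IMPUTABLE = ["education_level"]
_EDU_LEVELS = ["middle_school_or_below", "high_school", "college_or_above"]


def _pmm_draw(rng, pred_obs, y_obs, pred_mis, k: int = 5) -> np.ndarray:
    """Predictive mean matching: for each missing prediction pick one of
    the k observed rows with the closest predictions."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n = len(sorted_y)
    out = np.empty(len(pred_mis))
    for i, p in enumerate(pos):
        lo = max(0, min(p - k // 2, n - k))
        out[i] = sorted_y[lo + rng.integers(min(k, n))]
    return out


def _design(df: pd.DataFrame, exclude: str, smoker_cols: bool) -> np.ndarray:
    cols = [
        df["age"].to_numpy(dtype=float),
        (df["sex"] == "male").to_numpy(dtype=float),
        df["bmi"].to_numpy(dtype=float),
        df["height"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=float),
        df["time"].to_numpy(dtype=float),
        pd.Categorical(df["education_level"], categories=_EDU_LEVELS).codes.astype(float),
    ]
    if smoker_cols:
        cols += [df[c].to_numpy(dtype=float)
                 for c in ("smoking_years", "quit_years", "cigarettes_per_day", "pack_years")]
    names = ["age", "sex", "bmi", "height", "event", "time", "education_level",
             "smoking_years", "quit_years", "cigarettes_per_day", "pack_years"]
    X = np.column_stack(cols)
    keep = [i for i, nm in enumerate(names[:X.shape[1]]) if nm != exclude]
    return X[:, keep]


def mice_impute(cohort: Cohort, m: int, seed: int, max_iter: int = 5) -> list[Cohort]:
    """Chained-equation imputation producing ``m`` complete cohorts.

    Continuous fields use linear regression with predictive mean matching;
    the categorical education field uses multinomial logistic sampling.
    Observed values are never modified.  Smoker-only fields are imputed
    within ever smokers only.
    """
    if max_iter > 10:
        max_iter = 10
    base = cohort.df
    ever = base["smoking_status"].isin(["current", "former"]).to_numpy()
    work_cols = []
    for col in _CONTINUOUS_IMPUTABLE + _CATEGORICAL_IMPUTABLE:
        applicable = ever if col in SMOKER_ONLY_COLUMNS else np.ones(len(base), bool)
        miss = base[col].isna().to_numpy() & applicable
        if miss.any():
            if miss.sum() == applicable.sum():
                raise ImputationError(f"field {col!r} is 100% missing; cannot impute")
            work_cols.append((col, miss, applicable))
    if not work_cols:
        return [Cohort(base.copy(), provenance=dict(cohort.provenance), validate=False)
                for _ in range(m)]

    out = []
    for j in range(m):
        rng = np.random.default_rng([int(seed), 4000 + j])
        df = base.copy()
        # initialize: means / modes over observed applicable rows
        for col, miss, applicable in work_cols:
            obs = applicable & ~base[col].isna().to_numpy()
            if col in _CATEGORICAL_IMPUTABLE:
                mode = base.loc[obs, col].mode().iloc[0]
                df.loc[miss, col] = mode
            elif col == "quit_years":
                cur = (base["smoking_status"] == "current").to_numpy()
                df.loc[miss & cur, col] = 0.0
                fill = float(base.loc[obs, col].mean())
                df.loc[miss & ~cur, col] = fill
            else:
                df.loc[miss, col] = float(base.loc[obs, col].mean())
        for _ in range(max_iter):
            for col, miss, applicable in work_cols:
                obs = applicable & ~base[col].isna().to_numpy()
                target_miss = miss.copy()
                if col == "quit_years":
                    # current smokers are structurally 0, nothing to model
                    target_miss &= (base["smoking_status"] == "former").to_numpy()
                    obs &= (base["smoking_status"] == "former").to_numpy()
                    if not target_miss.any():
                        continue
                X = _design(df, exclude=col, smoker_cols=col in SMOKER_ONLY_COLUMNS)
                # never-smoker rows carry structural NaN in smoker columns
                # but are never indexed; standardize over observed values
                mu, sd = np.nanmean(X, axis=0), np.nanstd(X, axis=0)
                X = (X - mu) / np.where(sd > 0, sd, 1.0)
                if col in _CATEGORICAL_IMPUTABLE:
                    y_obs = pd.Categorical(df.loc[obs, col], categories=_EDU_LEVELS).codes
                    if len(np.unique(y_obs)) < 2:
                        continue
                    clf = LogisticRegression(max_iter=500)
                    clf.fit(X[obs], y_obs)
                    proba = clf.predict_proba(X[target_miss])
                    cum = proba.cumsum(axis=1)
                    u = rng.uniform(size=len(proba))[:, None]
                    draw = (u > cum).sum(axis=1)
                    levels = np.array(_EDU_LEVELS, dtype=object)
                    classes = clf.classes_
                    df.loc[target_miss, col] = levels[classes[draw]]
                else:
                    reg = LinearRegression()
                    y_obs = df.loc[obs, col].to_numpy(dtype=float)
                    reg.fit(X[obs], y_obs)
                    pred_obs = reg.predict(X[obs])
                    pred_mis = reg.predict(X[target_miss])
                    df.loc[target_miss, col] = _pmm_draw(rng, pred_obs, y_obs, pred_mis)
        prov = dict(cohort.provenance)
        prov["imputation"] = {"m_index": j, "m": m, "seed": int(seed)}
        out.append(Cohort(df, provenance=prov, validate=False))
    return out


# ---------------------------------------------------------------------------
# report assembly

def outcomes_at_horizon(cohort_or_df, t: float, censor_policy: str = "include"):
    """(outcome vector, keep mask) for the horizon-t case definition."""
    df = cohort_or_df.df if isinstance(cohort_or_df, Cohort) else cohort_or_df
    event = df["event"].to_numpy(dtype=bool)
    time = df["time"].to_numpy(dtype=float)
    y = event & (time <= t)
    if censor_policy == "exclude":
        keep = ~(~event & (time < t))
    elif censor_policy == "include":
        keep = np.ones(len(y), bool)
    else:
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    return y, keep


@dataclass
class ValidationReport:
    model: str
    stratum: str
    horizon: float
    n: int
    auc: float
    auc_ci: tuple[float, float]
    expected: float
    observed: int
    eo_ratio: float
    eo_ci: tuple[float, float]
    calibration: list = dc_field(default_factory=list)
    n_imputations: int = 1

    def to_dict(self) -> dict:
        return {
            "model": self.model, "stratum": self.stratum, "horizon": self.horizon,
            "n": self.n, "auc": self.auc, "auc_ci": list(self.auc_ci),
            "expected": self.expected, "observed": self.observed,
            "eo_ratio": self.eo_ratio, "eo_ci": list(self.eo_ci),
            "calibration": self.calibration, "n_imputations": self.n_imputations,
        }


def validate_model(cohort: Cohort, spec, stratum: str = "all", m: int = 5, seed: int = 0,
                   horizon: float | None = None, censor_policy: str = "include",
                   rescale: str = "none", imputations: list | None = None) -> ValidationReport:
    """Score one model on one cohort stratum, pooling over imputations.

    If the cohort contains missing values in the imputable fields, MICE
    produces ``m`` completed copies and AUC / log(E/O) are pooled with
    Rubin's rules; otherwise a single pass is used.

    ``horizon`` overrides the evaluation horizon for the outcome
    definition (the model's native risk is used as the score unless
    ``rescale="linear"``, which scales expected counts by t / native).
    """
    from .engines import score_cohort
    from .cohort import subset_by_smoking

    t = float(horizon) if horizon is not None else float(spec.horizon)
    if imputations is not None:
        cohorts = list(imputations)
    else:
        if stratum in ("ever", "never"):
            cohort = subset_by_smoking(cohort, stratum)
        needs_mice = any(cohort.df[c].isna().to_numpy()[
            cohort.df["smoking_status"].isin(["current", "former"]).to_numpy()
            if c in SMOKER_ONLY_COLUMNS else slice(None)].any()
            for c in _CONTINUOUS_IMPUTABLE + _CATEGORICAL_IMPUTABLE)
        cohorts = mice_impute(cohort, m=m, seed=seed) if needs_mice else [cohort]

    aucs, auc_vars, log_ratios, log_vars = [], [], [], []
    risks_accum = None
    expected = observed = n_eff = None
    for c in cohorts:
        scored = score_cohort(spec, c, on_population="error")
        risks = scored["risk"].to_numpy()
        if rescale == "linear" and horizon is not None:
            risks = np.clip(risks * t / float(spec.horizon), 0.0, 1.0)
        y, keep = outcomes_at_horizon(c, t, censor_policy)
        risks, y = risks[keep], y[keep]
        a, v = auc_delong_variance(risks, y)
        eo = eo_ratio(risks, y)
        aucs.append(a)
        auc_vars.append(v)
        log_ratios.append(np.log(eo["eo_ratio"]))
        log_vars.append(1.0 / eo["observed"])
        expected, observed, n_eff = eo["expected"], eo["observed"], len(y)
        risks_accum = risks if risks_accum is None else risks_accum + risks

    z = norm.ppf(0.975)
    if len(cohorts) > 1:
        pa = rubin_pool(aucs, auc_vars)
        auc_point, (alo, ahi) = pa.point, pa.ci()
        pr = rubin_pool(log_ratios, log_vars)
        ratio = float(np.exp(pr.point))
        rlo, rhi = np.exp(pr.ci())
        expected = ratio * observed
    else:
        auc_point = aucs[0]
        half = z * np.sqrt(auc_vars[0])
        alo, ahi = auc_point - half, auc_point + half
        ratio = float(np.exp(log_ratios[0]))
        rlo = ratio * float(np.exp(-z * np.sqrt(log_vars[0])))
        rhi = ratio * float(np.exp(z * np.sqrt(log_vars[0])))

    mean_risks = risks_accum / len(cohorts)
    y_last, _ = outcomes_at_horizon(cohorts[-1], t, censor_policy)
    y_last = y_last[keep]
    bins = calibration_bins(mean_risks, y_last)

    return ValidationReport(
        model=spec.name, stratum=stratum, horizon=t, n=int(n_eff),
        auc=float(auc_point), auc_ci=(float(np.clip(alo, 0, 1)), float(np.clip(ahi, 0, 1))),
        expected=float(expected), observed=int(observed),
        eo_ratio=float(ratio), eo_ci=(float(rlo), float(rhi)),
        calibration=bins.to_dict(orient="records"),
        n_imputations=len(cohorts),
    )


# ---------------------------------------------------------------------------
# high-risk group feature table

_DEFAULT_FEATURES = {
    "sex": {"kind": "categorical"},
    "age": {"kind": "bin", "breaks": [50, 55, 60, 65, 70, 75, 80, 85, 90],
            "labels": ["45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
                       "75-79", "80-84", "85-89", ">=90"]},
    "bmi": {"kind": "bin", "breaks": [18.5, 24], "labels": ["<18.5", "18.5-23.9", ">=24"]},
    "education_level": {"kind": "categorical"},
    "prior_cancer": {"kind": "bool"},
    "emphysema": {"kind": "bool"},
    "copd": {"kind": "bool"},
    "family_history_lc": {"kind": "categorical"},
    "smoking_status": {"kind": "categorical"},
    "smoking_years": {"kind": "bin", "breaks": [10, 20, 30, 40, 50, 60],
                      "labels": ["<10", "10-19", "20-29", "30-39", "40-49", "50-59", ">=60"]},
    "pack_years": {"kind": "bin", "breaks": [20, 40],
                   "labels": ["<20", "20-39", ">=40"]},
    "cigarettes_per_day": {"kind": "bin", "breaks": [10, 15, 20, 25, 30, 35],
                           "labels": ["<10", "10-14", "15-19", "20-24", "25-29",
                                      "30-34", ">=35"]},
}


def radial_feature_summary(cohort: Cohort, high_risk_ids, features: dict | None = None) -> pd.DataFrame:
    """Percentage composition of the high-risk group per feature category.

    Continuous features are binned with the published group boundaries.
    Within each feature, percentages are over the subjects with an
    applicable (non-missing) value and sum to 100.
    """
    ids = set(high_risk_ids)
    if not ids:
        raise DataError("empty high-risk set")
    unknown = ids - set(cohort.df["id"])
    if unknown:
        raise DataError(f"{len(unknown)} high-risk id(s) not in cohort")
    sub = cohort.df[cohort.df["id"].isin(ids)]
    features = features or _DEFAULT_FEATURES
    rows = []
    for feat, cfg in features.items():
        col = sub[feat]
        if cfg["kind"] == "bool":
            labels = pd.Series(np.where(col.astype("boolean").fillna(False), "yes", "no"),
                               index=col.index)[col.notna()]
        elif cfg["kind"] == "bin":
            vals = pd.to_numeric(col, errors="coerce")
            labels = pd.Series(
                np.asarray(cfg["labels"], dtype=object)[
                    np.searchsorted(np.asarray(cfg["breaks"], dtype=float),
                                    vals.to_numpy(dtype=float), side="right")],
                index=col.index)[vals.notna()]
        else:
            labels = col[col.notna()].astype(str)
        total = len(labels)
        if total == 0:
            continue
        counts = labels.value_counts()
        for cat, n in counts.items():
            rows.append({"feature": feat, "category": cat, "n": int(n),
                         "percentage": 100.0 * n / total})
    return pd.DataFrame(rows)
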