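"""Subject/follow-up domain model and CSV round-trip I/O.

A cohort is stored column-wise as a :class:`pandas.DataFrame` (one row per
subject) plus provenance metadata.  :class:`SubjectRecord` and
:class:`FollowUp` are the row-level views used by single-subject APIs.

Missing-value conventions
-------------------------
* In memory, a missing value is ``NaN`` / ``pd.NA``.
* Smoker-only fields of never smokers are *not applicable*, not missing;
  in memory they are also ``NA`` but are written to CSV as ``"—"`` while
  genuinely missing cells are written as the empty string.  On read both
  map back to ``NA``; applicability is derived from ``smoking_status``.
"""

from __future__ import annotations

import csv as _csv
import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import CohortFormatError, RowValidationError

__all__ = [
    "SubjectRecord",
    "FollowUp",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "subset_by_smoking",
    "load_column_map",
    "SUBJECT_COLUMNS",
    "SMOKER_ONLY_COLUMNS",
]

# Canonical column order (subject predictors, then follow-up).
SUBJECT_COLUMNS = [
    "id",
    "sex",
    "age",
    "height",
    "bmi",
    "education_level",
    "smoking_status",
    "age_started",
    "smoking_years",
    "quit_years",
    "cigarettes_per_day",
    "pack_years",
    "inhale_to_lungs",
    "secondhand_smoke_hours_per_day",
    "alcohol_days_per_week",
    "physical_activity_minutes_per_week",
    "physical_activity_sessions_per_week",
    "family_history_lc",
    "asbestos_exposure",
    "prior_cancer",
    "copd",
    "chronic_bronchitis",
    "emphysema",
    "interstitial_lung_disease",
    "diabetes",
    "cough",
]
FOLLOWUP_COLUMNS = ["event", "time"]
ALL_COLUMNS = SUBJECT_COLUMNS + FOLLOWUP_COLUMNS

SMOKER_ONLY_COLUMNS = [
    "age_started",
    "smoking_years",
    "quit_years",
    "cigarettes_per_day",
    "pack_years",
    "inhale_to_lungs",
]

NUMERIC_COLUMNS = [
    "age",
    "height",
    "bmi",
    "age_started",
    "smoking_years",
    "quit_years",
    "cigarettes_per_day",
    "pack_years",
    "secondhand_smoke_hours_per_day",
    "alcohol_days_per_week",
    "physical_activity_minutes_per_week",
    "physical_activity_sessions_per_week",
    "time",
]
BOOL_COLUMNS = [
    "inhale_to_lungs",
    "asbestos_exposure",
    "prior_cancer",
    "copd",
    "chronic_bronchitis",
    "emphysema",
    "interstitial_lung_disease",
    "diabetes",
    "cough",
    "event",
]
CATEGORICAL_DOMAINS = {
    "sex": {"male", "female"},
    "education_level": {"middle_school_or_below", "high_school", "college_or_above"},
    "smoking_status": {"never", "current", "former"},
    "family_history_lc": {"none", "first_degree"},
}

#: CSV tokens interpreted as missing / not-applicable on input.
MISSING_TOKENS = {"", "—", "-", "NA", "N/A", "na", "nan", "NaN"}
NA_SENTINEL = "—"  # written for not-applicable smoker-only cells


@dataclass
class SubjectRecord:
    """One participant's predictor set.  ``None`` marks a missing value."""

    id: str
    sex: str | None = None
    age: int | None = None
    height: float | None = None
    bmi: float | None = None
    education_level: str | None = None
    smoking_status: str | None = None
    age_started: float | None = None
    smoking_years: float | None = None
    quit_years: float | None = None
    cigarettes_per_day: float | None = None
    pack_years: float | None = None
    inhale_to_lungs: bool | None = None
    secondhand_smoke_hours_per_day: float | None = None
    alcohol_days_per_week: float | None = None
    physical_activity_minutes_per_week: float | None = None
    physical_activity_sessions_per_week: float | None = None
    family_history_lc: str | None = None
    asbestos_exposure: bool | None = None
    prior_cancer: bool | None = None
    copd: bool | None = None
    chronic_bronchitis: bool | None = None
    emphysema: bool | None = None
    interstitial_lung_disease: bool | None = None
    diabetes: bool | None = None
    cough: bool | None = None

    @property
    def is_ever_smoker(self) -> bool | None:
        if self.smoking_status is None:
            return None
        return self.smoking_status in ("current", "former")

    def get(self, name: str):
        return getattr(self, name)


@dataclass
class FollowUp:
    """Incident lung-cancer outcome: event indicator and time (years, > 0)."""

    event: bool
    time: float


def _na_to_none(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if v is pd.NA:
        return None
    return v


class Cohort:
    """Ordered collection of (SubjectRecord, FollowUp) pairs.

    Parameters
    ----------
    df : DataFrame with the canonical columns (:data:`ALL_COLUMNS`).
    provenance : free-form metadata (source file, generator config, seed).
    validate : run hard-invariant validation on construction.
    """

    def __init__(self, df: pd.DataFrame, provenance: dict | None = None, validate: bool = True):
        missing_cols = [c for c in ALL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortFormatError(f"missing mandatory columns: {missing_cols}")
        df = df[ALL_COLUMNS].reset_index(drop=True)
        df = _coerce_dtypes(df)
        if validate:
            errors = validate_frame(df)
            if errors:
                raise RowValidationError(errors)
        self.df = df
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def iter_records(self) -> Iterator[tuple[SubjectRecord, FollowUp]]:
        names = [f.name for f in dc_fields(SubjectRecord)]
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            subj = SubjectRecord(**{k: _na_to_none(d[k]) for k in names})
            yield subj, FollowUp(event=bool(d["event"]), time=float(d["time"]))

    def subset(self, mask, provenance_note: str | None = None) -> "Cohort":
        sub = self.df.loc[np.asarray(mask)].reset_index(drop=True)
        prov = dict(self.provenance)
        if provenance_note:
            prov.setdefault("subsets", []).append(provenance_note)
        return Cohort(sub, provenance=prov, validate=False)

    def equals(self, other: "Cohort") -> bool:
        if len(self) != len(other):
            return False
        a, b = self.df, other.df
        for col in ALL_COLUMNS:
            x, y = a[col], b[col]
            if col in NUMERIC_COLUMNS or col == "age":
                if not np.array_equal(x.to_numpy(dtype=float), y.to_numpy(dtype=float), equal_nan=True):
                    return False
            else:
                if not (x.isna() == y.isna()).all():
                    return False
                m = ~x.isna()
                if not (x[m] == y[m]).all():
                    return False
        return True

    def __eq__(self, other) -> bool:  # pragma: no cover - delegates
        return isinstance(other, Cohort) and self.equals(other)


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["id"] = df["id"].astype(str)
    for col in NUMERIC_COLUMNS + ["age"]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    for col in BOOL_COLUMNS:
        if df[col].dtype != "boolean":
            df[col] = df[col].astype("boolean")
    for col in CATEGORICAL_DOMAINS:
        df[col] = df[col].astype(object).where(~pd.isna(df[col]), np.nan)
    return df


def validate_frame(df: pd.DataFrame) -> list[tuple[str, str]]:
    """Check hard record invariants; return (id, message) diagnostics."""
    errors: list[tuple[str, str]] = []
    ids = df["id"].astype(str)

    dup = ids[ids.duplicated()]
    for rid in dup.unique():
        errors.append((rid, "duplicate id"))

    age = df["age"]
    bad = df.index[age.notna() & (age < 45)]
    errors += [(ids[i], f"age {age[i]} < 45") for i in bad]

    for col, domain in CATEGORICAL_DOMAINS.items():
        vals = df[col]
        bad = df.index[vals.notna() & ~vals.isin(domain)]
        errors += [(ids[i], f"{col}={vals[i]!r} not in {sorted(domain)}") for i in bad]

    never = df["smoking_status"] == "never"
    for col in SMOKER_ONLY_COLUMNS:
        bad = df.index[never & df[col].notna()]
        errors += [(ids[i], f"never smoker has {col}={df[col][i]!r}") for i in bad]

    current = df["smoking_status"] == "current"
    qy = df["quit_years"]
    bad = df.index[current & qy.notna() & (qy != 0)]
    errors += [(ids[i], f"current smoker has quit_years={qy[i]}") for i in bad]
    former = df["smoking_status"] == "former"
    bad = df.index[former & qy.notna() & (qy < 0)]
    errors += [(ids[i], f"former smoker has quit_years={qy[i]} < 0") for i in bad]

    t = df["time"]
    bad = df.index[t.notna() & (t <= 0)]
    errors += [(ids[i], f"follow-up time {t[i]} <= 0") for i in bad]
    bad = df.index[t.isna() | df["event"].isna()]
    errors += [(ids[i], "missing follow-up (event/time)") for i in bad]
    return errors


def load_column_map(path) -> dict[str, str]:
    """Load an external-header -> canonical-field mapping (YAML)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mapping = doc.get("columns", doc) if isinstance(doc, dict) else None
    if not isinstance(mapping, dict):
        raise CohortFormatError(f"column map {path} is not a mapping")
    unknown = [v for v in mapping.values() if v not in ALL_COLUMNS]
    if unknown:
        raise CohortFormatError(f"column map targets unknown fields: {unknown}")
    return {str(k): str(v) for k, v in mapping.items()}


_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n"}


def read_cohort(path, dialect: str | None = None, column_map: Mapping[str, str] | None = None,
                on_invalid: str = "raise") -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path : CSV file, RFC-4180, UTF-8, one row per subject.
    dialect : optional delimiter (single char) or csv dialect name.
    column_map : optional external-header -> canonical-field mapping.
    on_invalid : ``"raise"`` (default) aborts on invalid rows; ``"drop"``
        removes them and records diagnostics in ``provenance["row_errors"]``.
    """
    path = Path(path)
    if not path.exists():
        raise CohortFormatError(f"no such file: {path}")
    sep = ","
    if dialect:
        if len(dialect) == 1:
            sep = dialect
        else:
            sep = _csv.get_dialect(dialect).delimiter
    raw = pd.read_csv(path, dtype=str, sep=sep, keep_default_na=False, encoding="utf-8")
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing_cols = [c for c in ALL_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing mandatory columns: {missing_cols}")
    raw = raw[ALL_COLUMNS]

    parsed = pd.DataFrame(index=raw.index)
    row_errors: list[tuple[str, str]] = []
    ids = raw["id"].str.strip()
    parsed["id"] = ids

    def _clean(col):
        s = raw[col].str.strip()
        return s.where(~s.isin(MISSING_TOKENS), other=pd.NA)

    def _safe_float(v):
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in NUMERIC_COLUMNS + ["age"]:
        s = _clean(col)
        # parse with Python float: exact round-trip of repr() output
        num = s.map(_safe_float).astype(float)
        bad = raw.index[s.notna() & num.isna()]
        row_errors += [(ids[i], f"non-parsable numeric {col}={s[i]!r}") for i in bad]
        parsed[col] = num.astype(float)

    frac = parsed["age"].notna() & (parsed["age"] % 1 != 0)
    if frac.any():
        warnings.warn(f"{int(frac.sum())} fractional age(s) floored to integer years", stacklevel=2)
        parsed.loc[frac, "age"] = np.floor(parsed.loc[frac, "age"])

    for col in BOOL_COLUMNS:
        s = _clean(col).str.lower()
        out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
        out[s.isin(_TRUE_TOKENS)] = True
        out[s.isin(_FALSE_TOKENS)] = False
        bad = raw.index[s.notna() & ~s.isin(_TRUE_TOKENS | _FALSE_TOKENS)]
        row_errors += [(ids[i], f"non-parsable boolean {col}={s[i]!r}") for i in bad]
        parsed[col] = out

    for col in CATEGORICAL_DOMAINS:
        parsed[col] = _clean(col).astype(object).where(lambda s: s.notna(), np.nan)

    parsed = parsed[ALL_COLUMNS]
    row_errors += validate_frame(_coerce_dtypes(parsed))
    if row_errors:
        if on_invalid == "raise":
            raise RowValidationError(row_errors)
        bad_ids = {rid for rid, _ in row_errors}
        parsed = parsed[~parsed["id"].isin(bad_ids)].reset_index(drop=True)
    return Cohort(parsed, provenance={"source": str(path), "row_errors": row_errors}, validate=False)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV such that ``read_cohort`` recovers an equal cohort."""
    df = cohort.df
    out = pd.DataFrame(index=df.index, columns=ALL_COLUMNS, dtype=object)
    never = (df["smoking_status"] == "never").to_numpy()
    for col in ALL_COLUMNS:
        s = df[col]
        if col == "age":
            vals = ["" if pd.isna(v) else str(int(v)) for v in s]
        elif col in NUMERIC_COLUMNS:
            vals = ["" if pd.isna(v) else repr(float(v)) for v in s]
        elif col in BOOL_COLUMNS:
            vals = ["" if pd.isna(v) else ("true" if v else "false") for v in s]
        else:
            vals = ["" if (not isinstance(v, str) and pd.isna(v)) else str(v) for v in s]
        out[col] = list(vals)
    if never.any():
        for col in SMOKER_ONLY_COLUMNS:
            col_vals = out[col].to_numpy(dtype=object)
            col_vals[never] = NA_SENTINEL
            out[col] = col_vals
    out.to_csv(path, index=False, encoding="utf-8")


def subset_by_smoking(cohort: Cohort, group: str) -> Cohort:
    """Partition into ever (current + former) or never smokers."""
    if group not in ("ever", "never"):
        raise ValueError(f"group must be 'ever' or 'never', got {group!r}")
    status = cohort.df["smoking_status"]
    mask = (status == "never") if group == "never" else status.isin(["current", "former"])
    return cohort.subset(mask.to_numpy(), provenance_note=f"smoking={group}")
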