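import numpy as np
import pandas as pd
import pytest

from lungrisk.cohort import ALL_COLUMNS, Cohort
from lungrisk.registry import _parse_spec
from lungrisk.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def cohort30k(cfg):
    """Default synthetic cohort, seed 1 (complete, no missingness)."""
    return generate_cohort(cfg, seed=1)


@pytest.fixture(scope="session")
def ever_panel(cohort30k):
    from lungrisk.cohort import subset_by_smoking
    return subset_by_smoking(cohort30k, "ever")


@pytest.fixture(scope="session")
def never_panel(cohort30k):
    from lungrisk.cohort import subset_by_smoking
    return subset_by_smoking(cohort30k, "never")


def make_row(**kw):
    """A complete, valid ever-smoker row (dict) for frame construction."""
    row = {
        "id": "X1", "sex": "male", "age": 60.0, "height": 165.0, "bmi": 23.0,
        "education_level": "high_school", "smoking_status": "current",
        "age_started": 20.0, "smoking_years": 30.0, "quit_years": 0.0,
        "cigarettes_per_day": 20.0, "pack_years": 30.0, "inhale_to_lungs": True,
        "secondhand_smoke_hours_per_day": 0.0, "alcohol_days_per_week": 2.0,
        "physical_activity_minutes_per_week": 120.0,
        "physical_activity_sessions_per_week": 3.0,
        "family_history_lc": "none", "asbestos_exposure": False,
        "prior_cancer": False, "copd": False, "chronic_bronchitis": False,
        "emphysema": False, "interstitial_lung_disease": False,
        "diabetes": False, "cough": False, "event": False, "time": 12.0,
    }
    row.update(kw)
    if row["smoking_status"] == "never":
        for c in ("age_started", "smoking_years", "quit_years",
                  "cigarettes_per_day", "pack_years", "inhale_to_lungs"):
            if c not in kw:  # explicit values kept for invariant-violation tests
                row[c] = None
    return row


def make_cohort(rows, validate=True):
    df = pd.DataFrame(rows)
    for i, c in enumerate(ALL_COLUMNS):
        if c not in df.columns:
            df[c] = np.nan
    df = df[[c for c in ALL_COLUMNS]]
    return Cohort(df, validate=validate)


def make_subject(**kw):
    from lungrisk.cohort import SubjectRecord
    row = make_row(**kw)
    row.pop("event"), row.pop("time")
    return SubjectRecord(**row)


@pytest.fixture(scope="session")
def true_model():
    """All-population logistic spec used as simulation ground truth."""
    doc = {
        "schema_version": 1, "name": "TRUE", "population": "all", "horizon": 6,
        "form": "logistic_direct", "intercept": -2.8,
        "terms": [
            {"field": "age", "coef": 0.03, "transform": {"type": "center", "value": 62}},
            {"field": "copd", "coef": 0.4, "transform": {"type": "indicator"}},
            {"field": "smoking_status", "coef": 1.0,
             "transform": {"type": "categorical",
                           "mapping": {"never": 0.0, "former": 0.3, "current": 0.6}}},
        ],
    }
    return _parse_spec(doc, origin="<test>")
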