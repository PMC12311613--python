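import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lungrisk.errors import DataError, ImputationError, UndefinedMetricError
from lungrisk.synthetic import CohortConfig, inject_missingness
from lungrisk.validation import (
    auc,
    auc_ci,
    calibration_bins,
    eo_ratio,
    mice_impute,
    outcomes_at_horizon,
    radial_feature_summary,
    rubin_pool,
)

from conftest import make_cohort, make_row


def auc_bruteforce(scores, outcomes):
    """Exhaustive pairwise concordance with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos, neg = scores[y], scores[~y]
    total = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


# -- AUC --------------------------------------------------------------------

def test_auc_perfect_separation():
    assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0


def test_auc_constant_scores():
    assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5


def test_auc_six_subject_ties_bruteforce():
    scores = [0.1, 0.3, 0.3, 0.5, 0.5, 0.9]
    y = [0, 0, 1, 0, 1, 1]
    assert auc(scores, y) == pytest.approx(auc_bruteforce(scores, y), abs=1e-15)


def test_auc_no_cases_error():
    with pytest.raises(UndefinedMetricError):
        auc([1, 2], [0, 0])
    with pytest.raises(UndefinedMetricError):
        auc([1, 2], [1, 1])


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_auc_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    scores = rng.normal(size=n)
    y = rng.integers(0, 2, size=n).astype(bool)
    if not (y.any() and (~y).any()):
        return
    assert auc(np.exp(scores * 2) + 3, y) == pytest.approx(auc(scores, y), abs=1e-12)


def test_auc_ci_clipped_at_one():
    lo, hi = auc_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert hi == 1.0


def test_auc_ci_narrows_with_duplication():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=100)
    y = rng.uniform(size=100) < 0.3
    scores[y] += 1.0
    lo1, hi1 = auc_ci(scores, y)
    lo2, hi2 = auc_ci(np.tile(scores, 2), np.tile(y, 2))
    assert hi2 - lo2 < hi1 - lo1


def test_auc_ci_close_to_bootstrap():
    rng = np.random.default_rng(7)
    n = 120
    y = rng.uniform(size=n) < 0.35
    scores = rng.normal(size=n) + y * 1.1
    lo, hi = auc_ci(scores, y)
    boots = []
    for _ in range(10000):
        idx = rng.integers(n, size=n)
        yb = y[idx]
        if yb.any() and (~yb).any():
            boots.append(auc(scores[idx], yb))
    blo, bhi = np.percentile(boots, [2.5, 97.5])
    assert abs(lo - blo) < 0.02
    assert abs(hi - bhi) < 0.02


# -- E/O --------------------------------------------------------------------

def test_eo_exact_calibration():
    p = np.array([0.5, 0.5, 0.5, 0.5])
    y = np.array([1, 1, 0, 0], dtype=bool)
    assert eo_ratio(p, y)["eo_ratio"] == 1.0


def test_eo_direct_arithmetic():
    p = np.full(20, 0.25)  # E = 5
    y = np.zeros(20, dtype=bool)
    y[:10] = True  # O = 10
    res = eo_ratio(p, y)
    assert res["eo_ratio"] == pytest.approx(0.5)
    assert res["expected"] == pytest.approx(5.0)
    assert res["observed"] == 10
    z = 1.959963984540054
    assert res["eo_ci"][0] == pytest.approx(0.5 * np.exp(-z / np.sqrt(10)))


def test_eo_zero_observed_error():
    with pytest.raises(UndefinedMetricError):
        eo_ratio([0.1, 0.2], [False, False])


# -- calibration bins -------------------------------------------------------

def test_bins_equal_split_n8():
    p = np.linspace(0.1, 0.8, 8)
    bins = calibration_bins(p, np.zeros(8, bool))
    assert list(bins["n"]) == [2, 2, 2, 2]


def test_bins_n10_rule():
    bins = calibration_bins(np.arange(10) / 10, np.zeros(10, bool))
    assert list(bins["n"]) == [3, 3, 2, 2]


def test_bins_ascending_and_high_risk_label():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    y = rng.uniform(size=40) < p
    bins = calibration_bins(p, y)
    mp = list(bins["mean_predicted"])
    assert mp == sorted(mp)
    assert bins["high_risk"].iloc[-1]
    assert int(bins["n"].sum()) == 40


def test_bins_zero_outcomes():
    bins = calibration_bins(np.linspace(0, 1, 12), np.zeros(12, bool))
    assert (bins["observed_proportion"] == 0).all()


def test_bins_too_few_subjects():
    with pytest.raises(DataError):
        calibration_bins([0.1, 0.2, 0.3], [0, 0, 1])


# -- Rubin pooling ----------------------------------------------------------

def test_rubin_hand_example():
    pooled = rubin_pool([0.70, 0.74], [0.01, 0.01])
    assert pooled.point == pytest.approx(0.72)
    assert pooled.within_variance == pytest.approx(0.01)
    assert pooled.between_variance == pytest.approx(0.0008)
    assert pooled.total_variance == pytest.approx(0.01 + 1.5 * 0.0008)
    assert pooled.m == 2


def test_rubin_identical_estimates():
    pooled = rubin_pool([0.5, 0.5, 0.5], [0.02, 0.02, 0.02])
    assert pooled.between_variance == 0.0
    assert pooled.total_variance == pooled.within_variance


def test_rubin_single_imputation_error():
    with pytest.raises(DataError):
        rubin_pool([0.5], [0.01])


# -- outcomes at horizon ----------------------------------------------------

def test_outcomes_at_horizon_policies():
    c = make_cohort([
        make_row(id="A", event=True, time=3.0),
        make_row(id="B", event=True, time=7.0),
        make_row(id="C", event=False, time=4.0),
        make_row(id="D", event=False, time=12.0),
    ])
    y, keep = outcomes_at_horizon(c, 5.0)
    assert list(y) == [True, False, False, False]
    assert keep.all()
    y2, keep2 = outcomes_at_horizon(c, 5.0, censor_policy="exclude")
    assert list(keep2) == [True, True, False, True]


# -- MICE -------------------------------------------------------------------

def test_mice_no_missing_identity(never_panel):
    sub = never_panel.subset(never_panel.df.index < 400)
    out = mice_impute(sub, m=3, seed=1)
    assert len(out) == 3
    for c in out:
        assert c.equals(sub)


def test_mice_produces_m_complete_cohorts(cohort30k, cfg):
    c = inject_missingness(cohort30k, cfg, seed=2)
    sub = c  # full cohort
    out = mice_impute(sub, m=5, seed=2, max_iter=2)
    assert len(out) == 5
    for imp in out:
        ever = imp.df["smoking_status"].isin(["current", "former"])
        assert not imp.df.loc[:, ["bmi", "height", "education_level"]].isna().any().any()
        assert not imp.df.loc[ever, ["smoking_years", "quit_years",
                                     "cigarettes_per_day"]].isna().any().any()
        # observed values untouched
        obs = ~c.df["bmi"].isna()
        assert (imp.df.loc[obs, "bmi"] == c.df.loc[obs, "bmi"]).all()


def test_mice_fully_missing_field_errors(never_panel):
    sub = never_panel.subset(never_panel.df.index < 100)
    df = sub.df.copy()
    df["bmi"] = np.nan
    from lungrisk.cohort import Cohort
    with pytest.raises(ImputationError):
        mice_impute(Cohort(df, validate=False), m=2, seed=0)


def test_pooled_auc_on_complete_cohort_equals_single(ever_panel, true_model):
    """m imputed copies of a complete cohort leave the AUC unchanged."""
    from lungrisk.engines import score_cohort
    sub = ever_panel.subset(ever_panel.df.index < 2000)
    risks = score_cohort(true_model, sub)["risk"].to_numpy()
    y, _ = outcomes_at_horizon(sub, 6.0)
    base = auc(risks, y)
    copies = mice_impute(sub, m=4, seed=5)
    aucs = [auc(score_cohort(true_model, c)["risk"].to_numpy(),
                outcomes_at_horizon(c, 6.0)[0]) for c in copies]
    assert all(a == base for a in aucs)


# -- radial summary ---------------------------------------------------------

def test_radial_all_female():
    rows = [make_row(id=f"S{i}", sex="female") for i in range(4)]
    c = make_cohort(rows)
    tab = radial_feature_summary(c, {r["id"] for r in rows})
    sex = tab[tab["feature"] == "sex"]
    assert list(sex["category"]) == ["female"]
    assert sex["percentage"].iloc[0] == 100.0


def test_radial_percentages_sum_to_100(ever_panel):
    ids = set(ever_panel.df["id"].iloc[:500])
    tab = radial_feature_summary(ever_panel, ids)
    sums = tab.groupby("feature")["percentage"].sum()
    assert np.allclose(sums, 100.0)


def test_radial_hand_tabulated():
    rows = [
        make_row(id="A", copd=True, sex="male"),
        make_row(id="B", copd=True, sex="female"),
        make_row(id="C", copd=False, sex="female"),
        make_row(id="D", copd=False, sex="female"),
    ]
    c = make_cohort(rows)
    tab = radial_feature_summary(c, {"A", "B", "C", "D"})
    copd = tab[tab["feature"] == "copd"].set_index("category")["percentage"]
    assert copd["yes"] == 50.0 and copd["no"] == 50.0
    sex = tab[tab["feature"] == "sex"].set_index("category")["percentage"]
    assert sex["female"] == 75.0 and sex["male"] == 25.0


def test_radial_empty_set_errors(ever_panel):
    with pytest.raises(DataError):
        radial_feature_summary(ever_panel, set())
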