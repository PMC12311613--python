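import math

import numpy as np
import pytest

from lungrisk.engines import (
    evaluate_linear_predictor,
    predict,
    risk_annual_recursion,
    risk_cox,
    risk_logistic,
    risk_rr_incidence,
    score_cohort,
)
from lungrisk.errors import EvaluationError, PopulationError, SpecError
from lungrisk.registry import _parse_spec

from conftest import make_subject


def toy_spec(**over):
    doc = {
        "name": "TOY", "population": "ever_only", "horizon": 5,
        "form": "logistic_direct", "intercept": 0.0, "terms": [],
    }
    doc.update(over)
    return _parse_spec(doc, origin="<test>")


def recursion_oracle(h_lc, h_m, horizon):
    """Explicit outcome-tree enumeration: each path survives some years
    then terminates with the event; probabilities are per-path products."""
    total = 0.0
    for k in range(int(horizon)):
        prob = 1.0
        for j in range(k):
            prob *= (1.0 - h_lc[j]) * (1.0 - h_m[j])
        total += prob * h_lc[k]
    return total


# -- linear predictor -------------------------------------------------------

def test_lp_intercept_only():
    spec = toy_spec(intercept=2.5)
    assert evaluate_linear_predictor(spec, make_subject()) == 2.5


def test_lp_single_identity_term():
    spec = toy_spec(terms=[{"field": "bmi", "coef": 2.0,
                            "transform": {"type": "identity"}}])
    assert evaluate_linear_predictor(spec, make_subject(bmi=3.0)) == 6.0


def test_lp_mixed_terms_hand_computed():
    spec = toy_spec(intercept=-1.0, terms=[
        {"field": "age", "coef": 0.1, "transform": {"type": "center", "value": 50}},
        {"field": "pack_years", "coef": 0.5, "transform": {"type": "log", "offset": 1}},
        {"field": "copd", "coef": 0.7, "transform": {"type": "indicator"}},
        {"field": "sex", "coef": 1.0,
         "transform": {"type": "categorical", "mapping": {"male": 0.2, "female": 0.0}}},
    ])
    s = make_subject(age=60, pack_years=29.0, copd=True, sex="male")
    expected = -1.0 + 0.1 * 10 + 0.5 * math.log(30.0) + 0.7 + 0.2
    assert evaluate_linear_predictor(spec, s) == pytest.approx(expected, rel=1e-12)


def test_lp_bin_and_power_transforms():
    spec = toy_spec(terms=[
        {"field": "smoking_years", "coef": 1.0,
         "transform": {"type": "bin", "breaks": [10, 20], "values": [0.0, 0.5, 1.0]}},
        {"field": "cigarettes_per_day", "coef": -2.0,
         "transform": {"type": "power", "scale": 10, "exponent": -1, "center": 0.5}},
    ])
    s = make_subject(smoking_years=15.0, cigarettes_per_day=20.0)
    assert evaluate_linear_predictor(spec, s) == pytest.approx(0.5 - 2.0 * (0.5 - 0.5))


def test_lp_truncation():
    spec = toy_spec(terms=[{"field": "age", "coef": 1.0,
                            "transform": {"type": "identity"}, "truncate": [50, 70]}])
    assert evaluate_linear_predictor(spec, make_subject(age=85)) == 70.0


def test_missing_predictor_names_field():
    spec = toy_spec(terms=[{"field": "bmi", "coef": 1.0,
                            "transform": {"type": "identity"}}])
    with pytest.raises(EvaluationError, match="bmi"):
        evaluate_linear_predictor(spec, make_subject(bmi=None))


def test_never_smoker_vs_ever_only_population_error():
    spec = toy_spec()
    with pytest.raises(PopulationError):
        evaluate_linear_predictor(spec, make_subject(smoking_status="never"))


# -- elementary forms -------------------------------------------------------

def test_risk_logistic_zero():
    assert risk_logistic(0.0) == 0.5


def test_risk_logistic_closed_form():
    assert risk_logistic(math.log(1 / 3)) == pytest.approx(0.25, rel=1e-12)


def test_risk_logistic_saturation():
    assert risk_logistic(-50.0) < 1e-20


def test_risk_cox_basic():
    assert risk_cox(0.0, 0.99) == pytest.approx(0.01, rel=1e-12)


def test_risk_cox_s0_one_gives_zero():
    for lp in (-3.0, 0.0, 4.0):
        assert risk_cox(lp, 1.0) == 0.0


def test_risk_cox_constant_hazard_identity():
    lam, t, lp = 0.02, 6.0, 0.7
    s0 = math.exp(-lam * t)
    assert risk_cox(lp, s0) == pytest.approx(1 - math.exp(-lam * t * math.exp(lp)), rel=1e-12)


def test_risk_cox_invalid_s0():
    with pytest.raises(SpecError):
        risk_cox(0.0, 0.0)
    with pytest.raises(SpecError):
        risk_cox(0.0, 1.5)


def test_risk_rr_identity():
    assert risk_rr_incidence(1.0, 0.037) == pytest.approx(0.037, rel=1e-12)


def test_risk_rr_odds_algebra():
    # odds 0.01/0.99 doubled -> 0.0202..., back-converted
    expected = (0.02 / 0.99) / (1 + 0.02 / 0.99)
    assert risk_rr_incidence(2.0, 0.01) == pytest.approx(expected, rel=1e-12)
    assert risk_rr_incidence(2.0, 0.01) == pytest.approx(0.0198019801980198, rel=1e-10)


def test_risk_rr_zero_base():
    assert risk_rr_incidence(5.0, 0.0) == 0.0


def test_risk_rr_negative_rejected():
    with pytest.raises(SpecError):
        risk_rr_incidence(-0.1, 0.01)


def test_recursion_zero_hazard():
    assert risk_annual_recursion([0.0] * 10, [0.1] * 10, 10) == 0.0


def test_recursion_closed_form_no_competing():
    h = 0.03
    got = risk_annual_recursion([h] * 10, [0.0] * 10, 10)
    assert got == pytest.approx(1 - (1 - h) ** 10, rel=1e-14)


def test_recursion_matches_tree_enumeration():
    rng = np.random.default_rng(11)
    for _ in range(50):
        h_lc = rng.uniform(0, 0.2, size=10)
        h_m = rng.uniform(0, 0.3, size=10)
        got = risk_annual_recursion(h_lc, h_m, 10)
        assert got == pytest.approx(recursion_oracle(h_lc, h_m, 10), abs=1e-12)


def test_recursion_fractional_final_year():
    h_lc, h_m = [0.1, 0.2], [0.05, 0.1]
    expected = 0.1 + 0.9 * 0.95 * 0.2 * 0.5
    assert risk_annual_recursion(h_lc, h_m, 1.5) == pytest.approx(expected, rel=1e-12)


def test_recursion_converges_to_cox_with_substeps():
    lam, t, lp = 0.05, 6.0, 0.4
    steps = 12 * int(t)
    h = lam / 12 * math.exp(lp)
    got = risk_annual_recursion([h] * steps, [0.0] * steps, steps)
    want = 1 - math.exp(-lam * t * math.exp(lp))
    assert abs(got - want) < 1e-3


def test_recursion_invalid_hazard():
    with pytest.raises(SpecError):
        risk_annual_recursion([1.5], [0.0], 1)


def test_recursion_table_too_short():
    with pytest.raises(SpecError):
        risk_annual_recursion([0.1] * 3, [0.0] * 3, 5)


# -- predict dispatch -------------------------------------------------------

def test_predict_logistic_lp_zero():
    spec = toy_spec()
    pred = predict(spec, make_subject())
    assert pred.risk == 0.5
    assert pred.horizon == 5
    assert pred.model == "TOY"


def test_predict_population_error():
    with pytest.raises(PopulationError):
        predict(toy_spec(), make_subject(smoking_status="never"))


def test_predict_recursion_composes():
    table = {"age_breaks": [200], "male": [0.01, 0.01], "female": [0.01, 0.01]}
    mort = {"age_breaks": [200], "male": [0.05, 0.05], "female": [0.05, 0.05]}
    spec = toy_spec(form="annual_recursion", horizon=5,
                    baselines={"annual_lc_hazard": table, "annual_mort_hazard": mort})
    pred = predict(spec, make_subject())
    want = risk_annual_recursion([0.01] * 5, [0.05] * 5, 5)
    assert pred.risk == pytest.approx(want, rel=1e-12)


def test_predict_deterministic():
    spec = toy_spec(terms=[{"field": "bmi", "coef": 0.1,
                            "transform": {"type": "identity"}}])
    s = make_subject()
    assert predict(spec, s).risk == predict(spec, s).risk


def test_monotone_in_positive_coefficient():
    spec = toy_spec(terms=[{"field": "pack_years", "coef": 0.05,
                            "transform": {"type": "identity"}}])
    risks = [predict(spec, make_subject(pack_years=p)).risk for p in (0, 10, 20, 40, 80)]
    assert all(a < b for a, b in zip(risks, risks[1:]))


def test_score_cohort_subset_policy(cohort30k):
    from lungrisk.registry import get_model
    spec = get_model("PLCOm2012")
    with pytest.raises(PopulationError):
        score_cohort(spec, cohort30k, on_population="error")
    scored = score_cohort(spec, cohort30k, on_population="subset")
    assert len(scored) == 5826
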