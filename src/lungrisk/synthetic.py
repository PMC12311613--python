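"""Synthetic cohort generation with exact stratified marginals.

The generator works stratum by stratum (smoking group x case status).
Within a stratum every categorical variable is allocated *exactly* per its
configured count table (deterministic allocation, then an independent
seeded shuffle per variable), so every published cell count is reproduced
by construction.  Continuous variables are drawn from truncated normals
with the configured mean/SD, restricted to the subject's allocated
category bin where the variable also has a count table.  Joint dependence
beyond the stratum split is therefore not modelled, except that pack-years
is derived from intensity x duration (then rescaled so the stratum mean
matches its configured value) and quit-years respects the allocated
smoking-status category.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import ALL_COLUMNS, Cohort, SMOKER_ONLY_COLUMNS
from .errors import ConfigError, DataError

__all__ = [
    "CohortConfig",
    "default_config",
    "load_config",
    "generate_cohort",
    "inject_missingness",
    "simulate_outcomes",
]

_STRATUM_ORDER = ["ever_case", "ever_noncase", "never_case", "never_noncase"]


@dataclass
class CohortConfig:
    """Parsed generator configuration (see ``data/gbcs_structure.yaml``)."""

    raw: dict
    seed: int | None = None
    mode: str = "marginal_matching"
    true_model = None  # ModelSpec, risk_structure mode only

    def __post_init__(self):
        self.mode = self.raw.get("mode", self.mode)
        self.validate()

    @property
    def strata(self) -> dict:
        return self.raw["strata"]

    @property
    def bins(self) -> dict:
        return self.raw["bins"]

    @property
    def total_n(self) -> int:
        return int(self.raw["total_n"])

    @property
    def event_schedule(self) -> dict:
        return self.raw["event_schedule"]

    @property
    def missingness(self) -> dict:
        return self.raw.get("missingness", {"n_subjects": 0, "fields": []})

    def validate(self) -> None:
        raw = self.raw
        for key in ("strata", "bins", "total_n", "event_schedule"):
            if key not in raw:
                raise ConfigError(f"config missing section {key!r}")
        total = 0
        for name, st in raw["strata"].items():
            n = int(st["n"])
            total += n
            for var, counts in st.get("categorical", {}).items():
                s = sum(int(c) for c in counts.values())
                if s != n:
                    raise ConfigError(
                        f"stratum {name!r}: counts for {var!r} sum to {s}, expected {n}")
        if total != self.total_n:
            raise ConfigError(f"stratum sizes sum to {total}, total_n is {self.total_n}")
        sched = raw["event_schedule"]
        for group in ("ever", "never"):
            cum = list(sched[group])
            if any(b < a for a, b in zip(cum, cum[1:])):
                raise ConfigError(f"event schedule for {group!r} is not non-decreasing")
            n_cases = sum(int(st["n"]) for st in raw["strata"].values()
                          if st["smoking_group"] == group and st["case"])
            if cum and cum[-1] > n_cases:
                raise ConfigError(
                    f"event schedule for {group!r} exceeds case count {n_cases}")
        if self.mode not in ("marginal_matching", "risk_structure"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def with_overrides(self, **kwargs) -> "CohortConfig":
        cfg = CohortConfig(copy.deepcopy(self.raw), seed=self.seed, mode=self.mode)
        cfg.true_model = self.true_model
        for k, v in kwargs.items():
            setattr(cfg, k, v)
        return cfg


def default_config() -> CohortConfig:
    """The shipped cohort-structure config (exact published marginals)."""
    text = resources.files("lungrisk.data").joinpath("gbcs_structure.yaml").read_text()
    return CohortConfig(yaml.safe_load(text))


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return CohortConfig(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# sampling helpers

def _truncnorm(rng, mean, sd, lo, hi, size):
    if size == 0:
        return np.empty(0)
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _alloc_labels(rng, counts: dict) -> np.ndarray:
    labels = np.repeat([str(k) for k in counts], [int(v) for v in counts.values()])
    return rng.permutation(labels)


def _binned_continuous(rng, counts: dict, bins: dict, mean: float, sd: float) -> np.ndarray:
    """Exact bin counts, truncated-normal values within each bin, shuffled."""
    parts = []
    for label, c in counts.items():
        lo, hi = bins[str(label)]
        parts.append(_truncnorm(rng, mean, sd, lo, hi, int(c)))
    return rng.permutation(np.concatenate(parts)) if parts else np.empty(0)


def _bool_from_counts(rng, counts: dict) -> np.ndarray:
    vals = np.repeat([False, True], [int(counts.get("no", 0)), int(counts.get("yes", 0))])
    return rng.permutation(vals)


def _event_times(rng, n_cases: int, schedule: dict, group: str) -> np.ndarray:
    horizons = [float(h) for h in schedule["horizons"]]
    cum = [int(c) for c in schedule[group]]
    tmax = float(schedule.get("max_event_time", 19.75))
    edges = [0.0] + horizons
    per_interval = np.diff([0] + cum).tolist()
    times = []
    for (lo, hi), k in zip(zip(edges[:-1], edges[1:]), per_interval):
        times.append(rng.uniform(lo, hi, size=k))
    tail = n_cases - cum[-1]
    if tail < 0:
        raise ConfigError(f"schedule for {group!r} exceeds number of cases")
    times.append(rng.uniform(horizons[-1], tmax, size=tail))
    out = np.concatenate(times)
    # times must be strictly positive and within (0, tmax]
    return rng.permutation(np.clip(out, 1e-6, tmax))


def _generate_stratum(cfg: CohortConfig, name: str, seed: int) -> pd.DataFrame:
    st = cfg.strata[name]
    bins = cfg.bins
    defaults = cfg.raw.get("defaults", {})
    n = int(st["n"])
    cat = st["categorical"]
    cont = st.get("continuous", {})
    is_ever = st["smoking_group"] == "ever"
    rng = np.random.default_rng([seed, _STRATUM_ORDER.index(name)])

    df = pd.DataFrame(index=range(n))
    df["sex"] = _alloc_labels(rng, cat["sex"])
    age = _binned_continuous(rng, cat["age_group"], bins["age_group"],
                             cont["age"]["mean"], cont["age"]["sd"])
    df["age"] = np.floor(age).astype(float)
    hmean = defaults.get("height", {}).get("mean", 158.0)
    hsd = defaults.get("height", {}).get("sd", 8.0)
    df["height"] = _binned_continuous(rng, cat["height_group"], bins["height_group"], hmean, hsd)
    df["bmi"] = _binned_continuous(rng, cat["bmi_group"], bins["bmi_group"],
                                   cont["bmi"]["mean"], cont["bmi"]["sd"])
    df["education_level"] = _alloc_labels(rng, cat["education_level"])
    df["family_history_lc"] = _alloc_labels(rng, cat["family_history_lc"])

    # count variables sampled uniformly (integers) within their bin
    for col, var in [("alcohol_days_per_week", "alcohol_group"),
                     ("physical_activity_minutes_per_week", "pa_minutes_group"),
                     ("physical_activity_sessions_per_week", "pa_sessions_group")]:
        parts = []
        for label, c in cat[var].items():
            lo, hi = bins[var][str(label)]
            parts.append(rng.integers(int(lo), int(hi), size=int(c)).astype(float))
        df[col] = rng.permutation(np.concatenate(parts))

    for col in ["asbestos_exposure", "prior_cancer", "copd", "chronic_bronchitis",
                "emphysema", "interstitial_lung_disease", "diabetes", "cough"]:
        df[col] = pd.array(_bool_from_counts(rng, cat[col]), dtype="boolean")

    shs_lo, shs_hi = defaults.get("secondhand_smoke_bounds", [0.0, 12.0])
    shs = cont["secondhand_smoke_hours_per_day"]
    df["secondhand_smoke_hours_per_day"] = _truncnorm(rng, shs["mean"], shs["sd"], shs_lo, shs_hi, n)

    if is_ever:
        status_labels = _alloc_labels(rng, cat["smoking_status"])
        df["smoking_status"] = np.where(status_labels == "current", "current", "former")
        qmean, qsd = cont["quit_years"]["mean"], cont["quit_years"]["sd"]
        qlo1, qhi1 = defaults.get("quit_lt15_bounds", [0.5, 15.0])
        qlo2, qhi2 = defaults.get("quit_ge15_bounds", [15.0, 40.0])
        quit = np.zeros(n)
        m1 = status_labels == "former_lt15"
        m2 = status_labels == "former_ge15"
        quit[m1] = _truncnorm(rng, qmean, qsd, qlo1, qhi1, int(m1.sum()))
        quit[m2] = _truncnorm(rng, qmean, qsd, qlo2, qhi2, int(m2.sum()))
        df["quit_years"] = quit
        df["smoking_years"] = _binned_continuous(
            rng, cat["smoking_years_group"], bins["smoking_years_group"],
            cont["smoking_years"]["mean"], cont["smoking_years"]["sd"])
        df["cigarettes_per_day"] = _binned_continuous(
            rng, cat["cigarettes_per_day_group"], bins["cigarettes_per_day_group"],
            cont["cigarettes_per_day"]["mean"], cont["cigarettes_per_day"]["sd"])
        aslo, ashi = defaults.get("age_started", {}).get("bounds", [10.0, 40.0])
        asc = cont["age_started"]
        df["age_started"] = _truncnorm(rng, asc["mean"], asc["sd"], aslo, ashi, n)
        df["inhale_to_lungs"] = pd.array(_bool_from_counts(rng, cat["inhale_to_lungs"]), dtype="boolean")
        py = df["cigarettes_per_day"].to_numpy() / 20.0 * df["smoking_years"].to_numpy()
        target = cont["pack_years"]["mean"]
        scale = target / py.mean() if py.mean() > 0 else 1.0
        df["pack_years"] = py * scale
    else:
        for col in SMOKER_ONLY_COLUMNS:
            df[col] = pd.NA if col == "inhale_to_lungs" else np.nan
        df["inhale_to_lungs"] = pd.array([pd.NA] * n, dtype="boolean")
        df["smoking_status"] = "never"

    if st["case"]:
        df["event"] = pd.array([True] * n, dtype="boolean")
        df["time"] = _event_times(rng, n, cfg.event_schedule, st["smoking_group"])
    else:
        lo, hi = cfg.raw.get("censor_time_range", [10.0, 19.75])
        df["event"] = pd.array([False] * n, dtype="boolean")
        df["time"] = rng.uniform(lo, hi, size=n)
    return df


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Generate a cohort reproducing the configured marginals exactly.

    ``seed`` overrides ``config.seed``; the same (config, seed) pair always
    yields an identical cohort.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    seed = int(seed)
    frames = [_generate_stratum(config, name, seed) for name in _STRATUM_ORDER
              if name in config.strata]
    df = pd.concat(frames, ignore_index=True)
    rng = np.random.default_rng([seed, 1000])
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "id", [f"S{i:06d}" for i in range(1, len(df) + 1)])
    cohort = Cohort(df[ALL_COLUMNS], provenance={"generator": "lungrisk.synthetic",
                                                 "mode": config.mode, "seed": seed})
    if config.mode == "risk_structure":
        if config.true_model is None:
            raise ConfigError("risk_structure mode requires config.true_model")
        cohort = simulate_outcomes(cohort, config.true_model, seed=seed + 1)
    return cohort


def inject_missingness(cohort: Cohort, config: CohortConfig, seed: int | None = None) -> Cohort:
    """Set >=1 configured field to missing for exactly the configured
    number of subjects, selected uniformly at random (MCAR)."""
    miss = config.missingness
    n_subjects = int(miss.get("n_subjects", 0))
    fields = list(miss.get("fields", []))
    if n_subjects == 0:
        return Cohort(cohort.df.copy(), provenance=dict(cohort.provenance), validate=False)
    if n_subjects > len(cohort):
        raise ConfigError(f"missingness count {n_subjects} exceeds cohort size {len(cohort)}")
    unknown = [f for f in fields if f not in ALL_COLUMNS]
    if unknown:
        raise ConfigError(f"missingness fields not in schema: {unknown}")
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng([int(seed), 2000])

    df = cohort.df.copy()
    never = (df["smoking_status"] == "never").to_numpy()
    smoker_only = set(SMOKER_ONLY_COLUMNS)
    applicable = [[f for f in fields if not (never[i] and f in smoker_only)]
                  for i in range(len(df))]
    eligible_rows = np.array([i for i, fs in enumerate(applicable) if fs])
    if len(eligible_rows) < n_subjects:
        raise ConfigError("not enough subjects with an applicable field to blank")
    chosen = rng.choice(eligible_rows, size=n_subjects, replace=False)
    for i in chosen:
        f = applicable[i][rng.integers(len(applicable[i]))]
        df.iloc[i, df.columns.get_loc(f)] = (
            np.nan if f != "inhale_to_lungs" else pd.NA)
    prov = dict(cohort.provenance)
    prov["missingness"] = {"n_subjects": n_subjects, "fields": fields, "seed": int(seed)}
    return Cohort(df, provenance=prov, validate=False)


def simulate_outcomes(cohort: Cohort, true_model, seed: int) -> Cohort:
    """Replace outcomes with Bernoulli(risk) draws from ``true_model``.

    Events get a uniform time on (0, horizon]; non-events are censored at
    the horizon.  Expected case count is the sum of the model risks.
    """
    from .engines import score_cohort

    risks = score_cohort(true_model, cohort)["risk"].to_numpy()
    if np.any(risks < 0) or np.any(risks > 1) or np.any(~np.isfinite(risks)):
        raise DataError("true model produced risks outside [0, 1]")
    rng = np.random.default_rng([int(seed), 3000])
    events = rng.uniform(size=len(risks)) < risks
    horizon = float(true_model.horizon)
    times = np.full(len(risks), horizon)
    times[events] = rng.uniform(0.0, horizon, size=int(events.sum()))
    times = np.clip(times, 1e-6, None)
    df = cohort.df.copy()
    df["event"] = pd.array(events, dtype="boolean")
    df["time"] = times
    prov = dict(cohort.provenance)
    prov["outcomes"] = {"simulated_from": true_model.name, "seed": int(seed)}
    return Cohort(df, provenance=prov, validate=False)
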