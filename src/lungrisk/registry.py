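"""Declarative model-spec format and loader for the bundled risk models.

A model spec is a YAML document describing one absolute-risk calculator:
its eligible population, time horizon, mathematical form, linear-predictor
terms (field + transformation + coefficient) and baseline tables.  Specs
are data, not code: the four engine forms in :mod:`lungrisk.engines`
interpret them.

Each bundled spec records its source citation.  Specs flagged
``surrogate: true`` carry coefficients re-derived or approximated from the
original publication's reported effects rather than an exact transcription
(e.g. the OWL model, originally a gradient-boosted ensemble, is shipped as
a documented logistic surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .cohort import BOOL_COLUMNS, CATEGORICAL_DOMAINS, NUMERIC_COLUMNS, SUBJECT_COLUMNS
from .errors import SpecError

__all__ = ["ModelSpec", "Term", "load_spec", "registry_list", "get_model", "MODEL_NAMES"]

MODEL_NAMES = [
    "LCRAT", "LLPv2", "LLPv3", "Pittsburgh", "HUNT", "OWL",
    "LCRS", "PLCOm2012", "PLCOall2014", "NHIS", "LLPi", "Bach",
]

FORMS = {"logistic_direct", "cox_baseline", "rr_times_incidence", "annual_recursion"}
POPULATIONS = {"ever_only", "all"}
TRANSFORM_TYPES = {"identity", "center", "log", "power", "categorical", "indicator", "bin"}

_PREDICTOR_FIELDS = set(SUBJECT_COLUMNS) - {"id"}
_NUMERIC_FIELDS = set(NUMERIC_COLUMNS) - {"time"}
_BOOL_FIELDS = set(BOOL_COLUMNS) - {"event"}


@dataclass
class Term:
    """One linear-predictor term: coef x transform(field)."""

    field: str
    coef: float
    transform: dict
    truncate: tuple | None = None  # raw-value truncation (lo, hi), either may be None
    never_raw: float | None = None  # raw value substituted for never smokers

    @property
    def ttype(self) -> str:
        return self.transform["type"]


@dataclass
class ModelSpec:
    name: str
    population: str
    horizon: float
    form: str
    intercept: float
    terms: list[Term]
    baselines: dict = field(default_factory=dict)
    surrogate: bool = False
    source: str = ""
    schema_version: int = 1
    notes: str = ""

    def term_for(self, fieldname: str) -> Term | None:
        for t in self.terms:
            if t.field == fieldname:
                return t
        return None


def _validate_transform(tr: dict, fieldname: str, path: str) -> None:
    ttype = tr.get("type")
    if ttype not in TRANSFORM_TYPES:
        raise SpecError(f"unknown transform type {ttype!r}", path)
    if ttype == "center" and "value" not in tr:
        raise SpecError("center transform requires 'value'", path)
    if ttype == "power" and "exponent" not in tr:
        raise SpecError("power transform requires 'exponent'", path)
    if ttype == "bin":
        breaks, values = tr.get("breaks"), tr.get("values")
        if not breaks or not values or len(values) != len(breaks) + 1:
            raise SpecError("bin transform needs breaks and len(values)=len(breaks)+1", path)
        if sorted(breaks) != list(breaks):
            raise SpecError("bin breaks must be ascending", path)
    if ttype == "categorical":
        mapping = tr.get("mapping")
        if not isinstance(mapping, dict) or not mapping:
            raise SpecError("categorical transform requires a 'mapping'", path)
        domain = CATEGORICAL_DOMAINS.get(fieldname)
        if domain is not None:
            unknown = set(map(str, mapping)) - domain
            if unknown:
                raise SpecError(f"mapping keys {sorted(unknown)} outside domain of {fieldname}", path)
    numeric_only = {"center", "log", "power", "bin"}
    if ttype in numeric_only and fieldname not in _NUMERIC_FIELDS and fieldname != "age":
        raise SpecError(f"{ttype} transform requires a numeric field, got {fieldname!r}", path)
    if ttype == "indicator" and fieldname not in _BOOL_FIELDS:
        raise SpecError(f"indicator transform requires a boolean field, got {fieldname!r}", path)
    if ttype == "categorical" and fieldname not in CATEGORICAL_DOMAINS:
        raise SpecError(f"categorical transform requires a categorical field, got {fieldname!r}", path)


def _parse_spec(doc: dict, origin: str) -> ModelSpec:
    if not isinstance(doc, dict):
        raise SpecError(f"{origin}: spec document is not a mapping")
    for key in ("name", "population", "horizon", "form"):
        if key not in doc:
            raise SpecError(f"missing required key {key!r}", f"{origin}:{key}")
    if doc["form"] not in FORMS:
        raise SpecError(f"unknown form {doc['form']!r}", f"{origin}:form")
    if doc["population"] not in POPULATIONS:
        raise SpecError(f"unknown population {doc['population']!r}", f"{origin}:population")

    terms: list[Term] = []
    for i, t in enumerate(doc.get("terms", [])):
        path = f"{origin}:terms[{i}]"
        fieldname = t.get("field")
        if fieldname not in _PREDICTOR_FIELDS:
            raise SpecError(f"unknown predictor {fieldname!r}", path)
        tr = t.get("transform", {"type": "identity"})
        _validate_transform(tr, fieldname, path)
        trunc = t.get("truncate")
        if trunc is not None:
            if len(trunc) != 2:
                raise SpecError("truncate must be [lo, hi]", path)
            trunc = (trunc[0], trunc[1])
        terms.append(Term(field=fieldname, coef=float(t.get("coef", 0.0)),
                          transform=tr, truncate=trunc,
                          never_raw=t.get("never_raw")))

    baselines = doc.get("baselines", {}) or {}
    form = doc["form"]
    if form == "cox_baseline":
        s0 = baselines.get("s0")
        if s0 is None or not (0 < float(s0) <= 1):
            raise SpecError("cox_baseline requires baselines.s0 in (0, 1]", f"{origin}:baselines.s0")
    if form == "rr_times_incidence":
        _validate_age_sex_table(baselines.get("baseline_risk"), f"{origin}:baselines.baseline_risk",
                                lo=0.0, hi=1.0, hi_exclusive=True)
    if form == "annual_recursion":
        for key in ("annual_lc_hazard", "annual_mort_hazard"):
            _validate_age_sex_table(baselines.get(key), f"{origin}:baselines.{key}", lo=0.0, hi=1.0)

    return ModelSpec(
        name=str(doc["name"]),
        population=doc["population"],
        horizon=float(doc["horizon"]),
        form=form,
        intercept=float(doc.get("intercept", 0.0)),
        terms=terms,
        baselines=baselines,
        surrogate=bool(doc.get("surrogate", False)),
        source=str(doc.get("source", "")),
        schema_version=int(doc.get("schema_version", 1)),
        notes=str(doc.get("notes", "")),
    )


def _validate_age_sex_table(table, path, lo=0.0, hi=1.0, hi_exclusive=False) -> None:
    if not isinstance(table, dict):
        raise SpecError("missing age/sex table", path)
    breaks = table.get("age_breaks")
    if not breaks or sorted(breaks) != list(breaks):
        raise SpecError("age_breaks must be an ascending list", path)
    for sex in ("male", "female"):
        vals = table.get(sex)
        if not vals or len(vals) != len(breaks) + 1:
            raise SpecError(f"{sex} values must have len(age_breaks)+1 entries", path)
        for v in vals:
            ok = (lo <= v < hi) if hi_exclusive else (lo <= v <= hi)
            if not ok:
                raise SpecError(f"{sex} value {v} outside [{lo}, {hi}]", path)


def load_spec(path) -> ModelSpec:
    """Load and validate one model-spec YAML file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_spec(doc, origin=path.name)


def registry_list() -> list[ModelSpec]:
    """All bundled model specs, in canonical order."""
    specs = {}
    root = resources.files("lungrisk.models")
    for entry in root.iterdir():
        if entry.name.endswith(".yaml"):
            spec = _parse_spec(yaml.safe_load(entry.read_text()), origin=entry.name)
            specs[spec.name] = spec
    return [specs[name] for name in MODEL_NAMES if name in specs] + sorted(
        (s for n, s in specs.items() if n not in MODEL_NAMES), key=lambda s: s.name)


def get_model(name: str) -> ModelSpec:
    for spec in registry_list():
        if spec.name.lower() == name.lower():
            return spec
    raise SpecError(f"no bundled model named {name!r}; known: {MODEL_NAMES}")
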