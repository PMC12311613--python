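"""End-to-end orchestration: cohort -> imputation -> validation -> comparison.

The pipeline emits JSON/CSV data products (reports are the source of
truth; figures are conveniences generated from them elsewhere).  Every
artifact records the seed, a config hash and a schema version, and runs
are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import Cohort, read_cohort, subset_by_smoking
from .comparison import compare_all
from .criteria import CRITERIA_NAMES
from .errors import ConfigError
from .registry import MODEL_NAMES, registry_list
from .synthetic import default_config, generate_cohort, inject_missingness, load_config
from .validation import (
    _CATEGORICAL_IMPUTABLE,
    _CONTINUOUS_IMPUTABLE,
    mice_impute,
    radial_feature_summary,
    validate_model,
)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Pipeline run configuration."""

    cohort_path: str | None = None          # CSV input; None -> synthetic
    synthetic_config_path: str | None = None
    with_missingness: bool = True
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    strata: list[str] = field(default_factory=lambda: ["ever", "never"])
    criteria: list[str] = field(default_factory=lambda: list(CRITERIA_NAMES))
    m_imputations: int = 5
    seed: int = 0
    output_dir: str = "lungrisk_out"
    censor_policy: str = "include"
    horizon: float | None = None            # common-horizon evaluation, e.g. 6
    rescale: str = "none"

    def config_hash(self) -> str:
        blob = json.dumps(vars(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_cohort(cfg: RunConfig) -> Cohort:
    if cfg.cohort_path:
        return read_cohort(cfg.cohort_path)
    gc = load_config(cfg.synthetic_config_path) if cfg.synthetic_config_path else default_config()
    cohort = generate_cohort(gc, seed=cfg.seed)
    if cfg.with_missingness:
        cohort = inject_missingness(cohort, gc, seed=cfg.seed)
    return cohort


def run_pipeline(cfg: RunConfig) -> dict:
    """Run validation and comparison for every configured model/stratum.

    Returns the report bundle (also serialized under ``cfg.output_dir``).
    """
    unknown = [m for m in cfg.models if m not in MODEL_NAMES]
    if unknown:
        raise ConfigError(f"unknown model name(s): {unknown}; known: {MODEL_NAMES}")
    unknown = [c for c in cfg.criteria if c not in CRITERIA_NAMES]
    if unknown:
        raise ConfigError(f"unknown criteria: {unknown}; known: {CRITERIA_NAMES}")

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    cohort = _load_cohort(cfg)
    log.append({"stage": "cohort", "n": len(cohort)})

    specs = [s for s in registry_list() if s.name in cfg.models]
    has_missing = any(cohort.df[c].isna().any()
                      for c in _CONTINUOUS_IMPUTABLE + _CATEGORICAL_IMPUTABLE)
    imputed = (mice_impute(cohort, m=cfg.m_imputations, seed=cfg.seed)
               if has_missing else [cohort])
    log.append({"stage": "imputation", "m": len(imputed),
                "had_missing": bool(has_missing)})

    reports = []
    for stratum in cfg.strata:
        strat_imputed = ([subset_by_smoking(c, stratum) for c in imputed]
                         if stratum in ("ever", "never") else imputed)
        panel = subset_by_smoking(cohort, stratum) if stratum in ("ever", "never") else cohort
        for spec in specs:
            if spec.population == "ever_only" and stratum != "ever":
                continue  # NA cells: smoker-only models have no never/all panel
            rep = validate_model(panel, spec, stratum=stratum, m=cfg.m_imputations,
                                 seed=cfg.seed, horizon=cfg.horizon,
                                 censor_policy=cfg.censor_policy, rescale=cfg.rescale,
                                 imputations=strat_imputed)
            reports.append(rep.to_dict())
        log.append({"stage": f"validate[{stratum}]", "n": len(panel),
                    "models": sum(1 for r in reports if r["stratum"] == stratum)})

    comparisons = {}
    complete = imputed[0]
    for stratum in cfg.strata:
        panel = subset_by_smoking(complete, stratum) if stratum in ("ever", "never") else complete
        for crit in cfg.criteria:
            key = f"{stratum}_{crit}"
            try:
                comparisons[key] = compare_all(panel, crit, specs,
                                               censor_policy=cfg.censor_policy)
            except Exception as exc:  # empty selection etc.
                log.append({"stage": f"compare[{key}]", "error": str(exc)})

    # radial feature summaries for each model's top risk quartile (ever panel)
    radial = {}
    if "ever" in cfg.strata:
        from .engines import score_cohort
        import numpy as np
        panel = subset_by_smoking(complete, "ever")
        for spec in specs:
            scored = score_cohort(spec, panel, on_population="subset")
            order = np.argsort(scored["risk"].to_numpy(), kind="stable")
            top = order[-(len(order) // 4):]
            ids = scored["id"].to_numpy()[top]
            radial[spec.name] = radial_feature_summary(panel, ids).to_dict(orient="records")

    bundle = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "validation_reports": reports,
        "comparisons": {k: v.to_dict(orient="records") for k, v in comparisons.items()},
        "radial_summaries": radial,
        "log": log,
    }
    (outdir / "reports.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    for key, tbl in comparisons.items():
        tbl.to_csv(outdir / f"comparison_{key}.csv", index=False)
    return bundle
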