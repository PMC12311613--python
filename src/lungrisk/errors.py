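"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2 is a *user* error
(bad config / bad spec file); DataError -> 1 covers malformed or
inconsistent input data discovered at run time.
"""


class LungriskError(Exception):
    """Base class for all package errors."""


class ConfigError(LungriskError):
    """Invalid configuration (generator config, run config, CLI flags)."""


class SpecError(ConfigError):
    """Invalid model-spec file (schema violation, unknown predictor, bad baseline)."""

    def __init__(self, message: str, field_path: str | None = None):
        self.field_path = field_path
        if field_path:
            message = f"{message} (at {field_path})"
        super().__init__(message)


class DataError(LungriskError):
    """Malformed or internally inconsistent input data."""


class CohortFormatError(DataError):
    """File-level problem: missing mandatory columns, unreadable CSV."""


class RowValidationError(DataError):
    """One or more rows violate hard record invariants.

    ``errors`` is a list of (row_id, message) pairs.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        preview = "; ".join(f"{rid}: {msg}" for rid, msg in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {preview}{more}")


class EvaluationError(DataError):
    """A model could not be evaluated on a subject (e.g. missing predictor)."""


class PopulationError(EvaluationError):
    """Subject outside the model's eligible population (never smoker vs ever-only)."""


class EligibilityError(DataError):
    """A screening criterion could not be evaluated (missing required field)."""


class UndefinedMetricError(DataError):
    """Metric undefined on the given data (no cases, no controls, O = 0...)."""


class ImputationError(DataError):
    """Multiple imputation cannot proceed (e.g. a field 100% missing)."""
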