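"""Exception types shared across the package."""

from __future__ import annotations


class SchemaError(ValueError):
    """An input table does not match the canonical questionnaire schema."""


class ConfigError(ValueError):
    """A configuration file or parameter set is invalid."""


class MissingInputError(ValueError):
    """A required algorithm input is missing under the strict policy."""

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__(f"missing required inputs: {', '.join(self.fields)}")


class DegenerateStatisticError(ValueError):
    """A test statistic is undefined for the given data (e.g. zero variance)."""


class CalibrationError(RuntimeError):
    """A numerical calibration failed to converge."""
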