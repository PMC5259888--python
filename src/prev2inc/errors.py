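"""Exception and warning types shared across the package."""


class Prev2IncError(Exception):
    """Base class for all package errors."""


class DomainError(Prev2IncError, ValueError):
    """An input value lies outside its mathematical domain.

    Carries the name of the offending field so table-level callers can
    report which column of which stratum was bad.
    """

    def __init__(self, field: str, value, message: str = ""):
        self.field = field
        self.value = value
        msg = message or f"{field}={value!r} is outside its valid domain"
        super().__init__(msg)


class DegenerateStratumError(Prev2IncError, ValueError):
    """The incidence denominator is non-positive (no person-time at risk)."""


class NegativeRateError(Prev2IncError, ValueError):
    """A confidence interval was requested for a negative point estimate."""


class StratumMismatchError(Prev2IncError, KeyError):
    """Tables that must share a stratum set do not."""

    def __init__(self, missing, where: str = ""):
        self.missing = sorted(missing)
        self.where = where
        msg = f"strata missing from {where or 'table'}: {self.missing}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return self.args[0]


class DataConsistencyError(Prev2IncError, ValueError):
    """Inputs contradict each other (e.g. cause-specific > all-cause mortality)."""


class ConfigurationError(Prev2IncError, ValueError):
    """A configuration value is invalid or inconsistent with the data."""


class TrendFitError(Prev2IncError, ValueError):
    """The trend regression cannot be fitted (too few or collinear points)."""


class ParseError(Prev2IncError, ValueError):
    """A tabular input file failed validation; message cites file and row."""


class ZeroPrevalenceWarning(UserWarning):
    """Emitted when an entire sex group has zero prevalence everywhere."""
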