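"""Exception hierarchy for cohortnet."""


class CohortNetError(Exception):
    """Base class for all cohortnet errors."""


class ConfigurationError(CohortNetError):
    """A configuration value is missing, out of range, or inconsistent."""


class SimulationError(CohortNetError):
    """The synthetic-cohort generator cannot satisfy its contract."""


class InputError(CohortNetError):
    """Malformed or inconsistent user-supplied input data."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyNetworkError(CohortNetError):
    """No seed gene of a sample maps onto the interactome."""
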