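"""Exception hierarchy.

All lungbench errors derive from :class:`LungBenchError` so callers can catch
the package's failures with a single except clause while still distinguishing
user-input problems (validation/configuration/domain) from numerical ones.
"""


class LungBenchError(Exception):
    """Base class for all lungbench exceptions."""


class ValidationError(LungBenchError, ValueError):
    """An input object violates its invariants (e.g. fractions not summing to 1)."""


class ConfigurationError(LungBenchError, ValueError):
    """A configuration references something unknown or inconsistent."""


class DomainError(LungBenchError, ValueError):
    """Arguments are outside the mathematical domain of an operation."""


class FitError(LungBenchError, RuntimeError):
    """A regression or calibration could not be performed."""


class ExtractionError(LungBenchError, ValueError):
    """A breath summary could not be extracted from a flow trace."""


class EstimationError(LungBenchError, RuntimeError):
    """A time-constant estimate could not be produced."""


class NumericalError(LungBenchError, RuntimeError):
    """An iterative solver failed to converge."""
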