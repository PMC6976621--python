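"""Exception types shared across the package."""


class ReachRiskError(Exception):
    """Base class for package-specific errors."""


class ParameterError(ReachRiskError, ValueError):
    """An argument violates a precondition (e.g. sigma <= 0, non-finite endpoint)."""


class NoUniqueMaximumError(ReachRiskError, RuntimeError):
    """The expected-gain surface is flat; no unique optimal aim point exists."""


class InsufficientHistoryError(ReachRiskError, ValueError):
    """Fewer past endpoints than the variance-estimation window requires."""


class InsufficientDataError(ReachRiskError, ValueError):
    """Too few observations for a fit (e.g. < 3 points on one side of the split)."""


class DegenerateDataError(ReachRiskError, ValueError):
    """Zero-variance or otherwise degenerate input to a statistical test."""


class ConfigError(ReachRiskError, ValueError):
    """Malformed protocol / run configuration."""


class SchemaError(ReachRiskError, ValueError):
    """A trial-table file does not match the expected column schema."""
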