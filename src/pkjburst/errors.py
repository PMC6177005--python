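"""Exception hierarchy for pkjburst.

Every error raised on bad input names the violated constraint rather than
failing with a bare ValueError deep inside numpy.
"""


class PkjburstError(Exception):
    """Base class for all package errors."""


class ParameterError(PkjburstError, ValueError):
    """A generative or analysis parameter violates its invariant."""


class DegenerateTrainError(PkjburstError, ValueError):
    """A generated or supplied train is too short to analyze (< 2 spikes)."""


class InsufficientDataError(PkjburstError, ValueError):
    """Too few interspike intervals for a stable statistic."""


class InfeasibleTargetsError(PkjburstError, ValueError):
    """No parameter set in the chosen family can reach the target statistics."""


class ZeroVarianceError(PkjburstError, ValueError):
    """A statistical test is undefined because all observations are identical."""


class UnbalancedDesignError(PkjburstError, ValueError):
    """Two-way ANOVA requires a balanced condition x bin design."""


class ConfigError(PkjburstError, ValueError):
    """A configuration file is malformed or contains unknown keys."""


class SchemaError(PkjburstError, ValueError):
    """An input table is missing required columns or has unparseable values."""


class PresetNotFoundError(PkjburstError, KeyError):
    """Requested calibrated regime preset does not exist."""
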