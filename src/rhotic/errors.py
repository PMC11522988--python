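"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigurationError / ParameterError -> 2,
DataError -> 3, everything else -> 1.
"""


class RhoticError(Exception):
    """Base class for all package errors."""


class ParameterError(RhoticError, ValueError):
    """An argument value is outside its documented domain."""


class DataError(RhoticError, ValueError):
    """Input data violate a precondition (empty, degenerate, single-class...)."""


class ConfigurationError(RhoticError, ValueError):
    """A run configuration is invalid or insufficient (e.g. too few speakers)."""


class StateError(RhoticError, RuntimeError):
    """An operation was called before its prerequisites exist (untrained model...)."""


class TrainingError(RhoticError, RuntimeError):
    """Optimization failed (non-finite loss, divergence)."""
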