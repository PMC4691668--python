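"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config -> 2, data -> 3, estimation -> 4).
"""


class MRPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(MRPipeError):
    """Invalid configuration: a field violates its invariant."""


class DataError(MRPipeError):
    """Input data violate a precondition (missing file, bad column, non-positive exposure...)."""


class EstimationError(MRPipeError):
    """An estimator cannot be computed (rank deficiency, too few instruments...)."""
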