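"""Exception types shared across the package."""


class AdmixscanError(Exception):
    """Base class for all package errors."""


class ConfigError(AdmixscanError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class ParseError(AdmixscanError, ValueError):
    """An input file could not be parsed; message names the offending line."""


class ValidationError(AdmixscanError, ValueError):
    """Structurally valid input violates a precondition (sort order, bounds)."""


class SaturatedDistanceError(AdmixscanError, ValueError):
    """A log-transform distance is undefined because divergence is saturated."""


class UndefinedDistanceError(AdmixscanError, ValueError):
    """A pairwise distance has no usable sites."""


class UndefinedStatisticError(AdmixscanError, ValueError):
    """A statistic cannot be computed (e.g. no informative blocks)."""
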