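"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`ThermoRampError`, so callers (and the CLI) can distinguish
"your input or configuration is wrong" from genuine bugs.
"""


class ThermoRampError(Exception):
    """Base class for all errors raised by thermoramp."""


class ConfigurationError(ThermoRampError):
    """A configuration value is missing or inconsistent (e.g. an unmapped column)."""


class ParseError(ThermoRampError):
    """An input file could not be interpreted (non-numeric cells, bad dialect)."""


class ValidationError(ThermoRampError):
    """Parsed data violates an invariant (duplicate timestamps, unknown cuvette id)."""


class InsufficientDataError(ThermoRampError):
    """Too few points survive for the requested operation."""


class FittingError(ThermoRampError):
    """A regression is singular, non-finite or otherwise cannot be computed."""


class ModelSelectionError(ThermoRampError):
    """An information criterion is undefined for the given n, k or residuals."""


class StabilityError(ThermoRampError):
    """The fixed-step integrator would take steps too large to trust."""
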