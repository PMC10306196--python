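"""Exception hierarchy shared across the package."""


class VasoreactError(Exception):
    """Base class for all vasoreact errors."""


class TraceFormatError(VasoreactError):
    """A trace or pressure file does not conform to the documented dialect."""


class CoverageError(VasoreactError):
    """A trace violates an ordering or coverage invariant (e.g. < 180 s
    of post-deflation data, non-monotonic timestamps)."""


class ValidationError(VasoreactError):
    """Numeric inputs violate a precondition (non-positive diameter,
    SBP <= DBP, empty series, zero pair mean, ...)."""


class InsufficientDataError(VasoreactError):
    """Not enough beats inside a required window or bin."""


class ConfigError(VasoreactError):
    """A run configuration is inconsistent with the data or out of range."""
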