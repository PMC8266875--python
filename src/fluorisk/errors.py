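"""Exception hierarchy shared across the package."""


class FluoriskError(Exception):
    """Base class for all package errors."""


class SchemaError(FluoriskError):
    """A tabular input does not match the documented column schema."""


class ValidationError(FluoriskError):
    """A record, distribution spec, or scenario violates an invariant."""


class InsufficientDataError(FluoriskError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(FluoriskError):
    """Input has no variation (or no usable signal) for the requested operation."""
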