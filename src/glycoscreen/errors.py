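"""Exception hierarchy for screen-data validation and analysis."""


class GlycoScreenError(ValueError):
    """Base class for all package errors."""


class SchemaError(GlycoScreenError):
    """A file does not conform to the documented column schema."""


class PlateValidationError(GlycoScreenError):
    """A plate map or measurement table violates a structural invariant."""


class PlateQCError(GlycoScreenError):
    """A plate fails a quality-control precondition (e.g. non-positive
    control mean for a signed metric, or no background wells)."""


class DegenerateStatError(GlycoScreenError):
    """A statistic cannot be formed (zero MAD, zero SD, too few values)."""
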