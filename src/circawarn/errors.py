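"""Exception hierarchy.

Error classes are grouped so the CLI can map them onto distinct exit
codes: configuration/usage problems, data/schema problems, and numerical
or model-fitting problems.
"""


class CircawarnError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CircawarnError, ValueError):
    """Invalid configuration value; ``field`` names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DataError(CircawarnError, ValueError):
    """Malformed or contract-violating input data."""


class SchemaError(DataError):
    """A table is missing columns or violates a column contract."""


class AlignmentError(DataError):
    """Two inputs that must cover the same dates do not."""


class DegenerateWindowError(CircawarnError, ValueError):
    """A dichotomy-index window has no usable epochs on one side."""

    code = "degenerate-window"


class EmptyInBedError(DegenerateWindowError):
    code = "empty-in-bed"


class EmptyOutOfBedError(DegenerateWindowError):
    code = "empty-out-of-bed"


class BaselineUnavailableError(DataError):
    """No body-weight measurement precedes the first chemotherapy course."""


class InterpolationImpossibleError(DataError):
    """A series contains no observed value at all."""


class NumericalError(CircawarnError, RuntimeError):
    """Numerical failure during model fitting."""


class UnfittableError(NumericalError):
    """The discriminant cannot be fitted (e.g. a single class present)."""
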