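"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: usage errors are handled by click
itself (exit 2), schema/data problems exit 3, detection failures exit 4.
"""


class RespivolError(Exception):
    """Base class for all package errors."""


class GeometryError(RespivolError):
    """Invalid polygon or marker geometry (self-intersection, bad ordering)."""


class ParameterError(RespivolError):
    """A numeric parameter is outside its valid domain."""


class InvalidConfigurationError(RespivolError):
    """A requested synthetic configuration is physically infeasible."""


class DetectionError(RespivolError):
    """Marker detection could not produce the expected number of markers."""

    def __init__(self, message: str, n_found: int | None = None):
        super().__init__(message)
        self.n_found = n_found


class CalibrationError(RespivolError):
    """Detected markers cannot yield a valid metric scale."""


class SchemaError(RespivolError):
    """An input table is missing required columns or rows."""


class SingularFitError(RespivolError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column
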