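"""Exception hierarchy shared across the pipeline stages."""


class RumenBatchError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RumenBatchError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(RumenBatchError, KeyError):
    """A required measurement, column, or analyte is absent."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return str(self.args[0]) if self.args else ""


class UndefinedValueError(RumenBatchError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""


class DegenerateCurveError(RumenBatchError, ValueError):
    """A standard curve cannot be fitted (too few or collinear points)."""


class DegenerateGroupError(RumenBatchError, ValueError):
    """A replicate group collapsed (e.g. every bottle rejected)."""


class SchemaError(RumenBatchError, ValueError):
    """An input table does not conform to its declared schema."""
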