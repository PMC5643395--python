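"""Exception types shared across the package."""


class NucFretError(Exception):
    """Base class for all package errors."""


class ValidationError(NucFretError, ValueError):
    """Invalid input data or parameters."""


class UndefinedValueError(NucFretError, ArithmeticError):
    """A quantity is undefined for the given inputs (e.g. zero denominator).

    Carries an optional identifier of the offending well or burst.
    """

    def __init__(self, message: str, ident: str | None = None):
        self.ident = ident
        if ident is not None:
            message = f"{message} (id={ident})"
        super().__init__(message)


class FitError(NucFretError, RuntimeError):
    """A model fit failed in a way that cannot be reported as a result."""
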