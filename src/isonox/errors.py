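"""Exception hierarchy for the isonox pipeline."""


class IsonoxError(Exception):
    """Base class for all isonox errors."""


class InvalidInputError(IsonoxError, ValueError):
    """A value violates a precondition (non-positive ratio, zero flux, ...)."""


class ConfigurationError(IsonoxError, ValueError):
    """Run configuration is inconsistent or incomplete."""


class SingularityError(IsonoxError, ArithmeticError):
    """The mixing-model denominator is (near-)zero: the observed air is
    isotopically indistinguishable from the pure soil end-member."""


class ParseError(IsonoxError, ValueError):
    """A data file violates its declared schema.

    Carries file/row/column context so the message pinpoints the offence.
    """

    def __init__(self, message: str, path=None, row=None, column=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if row is not None:
            ctx.append(f"row={row}")
        if column is not None:
            ctx.append(f"column={column}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path, self.row, self.column = path, row, column
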