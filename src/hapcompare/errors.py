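"""Exception hierarchy shared by all hapcompare modules."""


class HapCompareError(Exception):
    """Base class for all errors raised by hapcompare."""


class StructuralIntegrityError(HapCompareError):
    """A phasing result violates a structural invariant (e.g. a chromosomal
    position appears in more than one phase block)."""


class CoordinateError(HapCompareError):
    """A coordinate transformation would produce an illegal position (< 1)."""


class FormatError(HapCompareError):
    """A file could not be parsed in the declared dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(HapCompareError):
    """An operation that needs at least one record received none."""


class UsageError(HapCompareError):
    """Operation called with arguments that can never be valid together
    (e.g. comparing results from different chromosomes)."""
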