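"""Exception types shared across the package."""


class CytopanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CytopanError, ValueError):
    """A numeric or structural parameter is outside its legal range."""


class InvalidSequenceError(CytopanError, ValueError):
    """A nucleotide or amino-acid sequence contains illegal characters
    or violates a structural precondition (e.g. internal stop codon)."""


class InconsistentInputError(CytopanError, ValueError):
    """Two inputs that must agree (e.g. a CDS and its protein) do not."""


class MissingLeafError(CytopanError, KeyError):
    """A named leaf is absent from the tree."""


class ParseError(CytopanError, ValueError):
    """A file could not be parsed; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
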