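"""Exception hierarchy shared across the package."""


class ProbelinkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ProbelinkError):
    """A source line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SchemaError(ProbelinkError):
    """An input file lacks a required column or has the wrong shape."""


class BuildError(ProbelinkError):
    """The cross-reference store could not be built."""


class CatalogError(ProbelinkError):
    """A named gene set is unknown or a member list is invalid."""


class ExportError(ProbelinkError):
    """An IGV export selection cannot be satisfied."""
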