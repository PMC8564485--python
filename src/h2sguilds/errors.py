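"""Exception hierarchy shared across the package."""


class H2SGuildsError(Exception):
    """Base class for all package-specific errors."""


class CatalogSchemaError(H2SGuildsError):
    """A catalog file is structurally invalid (e.g. a required column is missing)."""


class CatalogValidationError(H2SGuildsError):
    """A catalog file parsed but violates a content invariant."""


class TableParseError(H2SGuildsError):
    """A tabular input file contains a malformed data row.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class HmmerParseError(TableParseError):
    """A HMMER tabular file contains a malformed data row."""


class ConsistencyError(H2SGuildsError):
    """Two inputs that must agree (sample sets, genome universes) do not."""


class DependencyError(H2SGuildsError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class DegenerateInputError(H2SGuildsError):
    """An input is syntactically valid but carries no usable signal
    (e.g. a taxonomic report with zero assigned reads)."""
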