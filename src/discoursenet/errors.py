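"""Exception hierarchy for the discourse-network pipeline."""


class DiscourseNetError(Exception):
    """Base class for all package errors."""


class SchemaError(DiscourseNetError):
    """A required column is missing or the file cannot be interpreted at all."""


class RowValidationError(DiscourseNetError):
    """One or more rows failed validation.

    Attributes
    ----------
    errors : list of (line_number, message)
        1-based line numbers in the source file (header = line 1).
    """

    def __init__(self, errors):
        self.errors = list(errors)
        summary = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} invalid row(s): {summary}{more}")


class EmptyInputError(DiscourseNetError):
    """The input file contains no statements."""


class MatrixFormatError(DiscourseNetError):
    """An adjacency-matrix file is non-square, asymmetric, or mislabelled."""


class ParameterError(DiscourseNetError):
    """A parameter is outside its valid range."""


class ConsistencyError(DiscourseNetError):
    """Inputs that must agree (network / partition / profile) do not."""
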