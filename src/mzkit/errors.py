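"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 2, NumericError -> 3.
"""


class MzkitError(Exception):
    """Base class for all package errors."""


class ValidationError(MzkitError):
    """Invalid input data, configuration, or file format."""


class FormatError(ValidationError):
    """Malformed file content (missing header keywords, bad cells)."""


class AlignmentError(ValidationError):
    """Raster layers with incompatible grid geometry."""


class NumericError(MzkitError):
    """Numerical failure: singular systems, non-convergence."""


class FitError(NumericError):
    """Model fitting did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
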