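"""Exception hierarchy shared across the package."""


class LncprogError(Exception):
    """Base class for all package-specific errors."""


class DomainError(LncprogError, ValueError):
    """Input violates a documented precondition (wrong range, empty group, ...)."""


class IdentityError(DomainError):
    """Duplicate or inconsistent gene/sample identifiers."""


class ParseError(LncprogError, ValueError):
    """Malformed cell or line in an input file; message carries coordinates."""


class MissingValueError(DomainError):
    """Missing expression values under the reject policy."""


class DegenerateSplitError(DomainError):
    """Mean split produced an empty stratum (constant biomarker)."""


class ConvergenceError(LncprogError, RuntimeError):
    """Iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, **diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics
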