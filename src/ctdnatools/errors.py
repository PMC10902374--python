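"""Typed exceptions raised by table readers and estimators."""


class CtdnaToolsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CtdnaToolsError):
    """A table is structurally malformed (missing column, undeclared level, ...)."""


class ValidationError(CtdnaToolsError):
    """A table row violates an invariant (negative count, VAF outside [0,1], ...)."""


class DomainError(CtdnaToolsError, ValueError):
    """A numeric argument lies outside the mathematical domain of a formula."""
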