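"""Exception hierarchy shared across the package."""


class FpkmKitError(Exception):
    """Base class for all package errors."""


class ParseError(FpkmKitError, ValueError):
    """Malformed input file (bad cell, empty file, missing column)."""


class ValidationError(FpkmKitError, ValueError):
    """Structurally parseable input that violates an invariant."""


class ArgumentError(FpkmKitError, ValueError):
    """Invalid argument supplied to an operation."""


class UndefinedFoldError(FpkmKitError, ValueError):
    """Fold change undefined because a group mean is zero."""


class DegenerateVarianceError(FpkmKitError, ValueError):
    """A statistical test received a group with zero variance."""


class NoOverlapError(FpkmKitError, ValueError):
    """A gene set shares no members with the ranked list."""


class ConfigError(FpkmKitError, ValueError):
    """Invalid pipeline configuration."""
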