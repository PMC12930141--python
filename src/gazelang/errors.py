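"""Exception hierarchy shared across the package."""


class GazelangError(Exception):
    """Base class for all package errors."""


class ConfigError(GazelangError):
    """Invalid or inconsistent configuration."""


class SchemaError(GazelangError):
    """Input table missing a required column or violating its declared schema."""


class RowParseError(GazelangError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(GazelangError):
    """A dependency tree violates tree structure (no root, two roots, cycle)."""


class DimensionError(GazelangError):
    """Embedding vectors with inconsistent dimensions."""


class SimilarityUndefinedError(GazelangError):
    """Similarity requested for degenerate input (empty sequence, zero vector)."""


class RegionMapError(GazelangError):
    """Scene missing from a region map, or malformed region definition."""


class DataError(GazelangError):
    """Input data violates an invariant (bad timestamps, duplicate trials)."""


class ConvergenceError(GazelangError):
    """Model fitting failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
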