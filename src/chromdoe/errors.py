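"""Exception hierarchy shared across the package.

Every module raises subclasses of :class:`ChromDoeError` so callers (the
CLI, the pipeline driver) can distinguish configuration mistakes from
data problems without string matching.
"""


class ChromDoeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChromDoeError):
    """An input specification (design size, goal definition, ...) is invalid."""


class CapacityError(ConfigurationError):
    """A design cannot host the requested number of factors."""


class ShapeError(ChromDoeError):
    """Dimension mismatch between arrays that must be conformable."""


class DomainError(ChromDoeError):
    """A numeric argument lies outside its mathematically valid domain."""


class SingularFitError(ChromDoeError):
    """The model matrix is rank deficient; carries the aliased term labels."""

    def __init__(self, message: str, aliased_terms: list[str] | None = None):
        super().__init__(message)
        self.aliased_terms = aliased_terms or []


class DataError(ChromDoeError):
    """Input data are unusable (too few points, non-finite values, ...)."""
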