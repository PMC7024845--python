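"""Exception hierarchy.

Exit-code mapping used by the CLI: ``ValidationError`` and
``ConfigurationError`` -> 1, ``ResolverError`` and I/O failures -> 2.
"""


class SecrepyError(Exception):
    """Base class for all package errors."""


class ValidationError(SecrepyError):
    """Input data violates a precondition (bad residue, empty sequence, ...)."""


class ConfigurationError(SecrepyError):
    """Invalid configuration (unknown column, key strategy, set arity, ...)."""


class ResolverError(SecrepyError):
    """The annotation store could not resolve one or more accessions."""

    def __init__(self, message: str, unresolved: list[str] | None = None):
        super().__init__(message)
        self.unresolved = list(unresolved or [])


class TransientResolverError(SecrepyError):
    """A retryable resolver failure (flaky storage, transient endpoint error)."""
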