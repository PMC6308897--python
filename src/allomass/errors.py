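"""Exception hierarchy shared across the package."""


class AllomassError(Exception):
    """Base class for all package-specific errors."""


class IntegrityError(AllomassError):
    """The embedded parameter database failed its load-time consistency checks."""


class ParameterLookupError(AllomassError, LookupError):
    """No parameter set exists for the requested model/taxon/region combination.

    ``fallback`` names the most informative model that *is* applicable with
    the information at hand, so callers can degrade gracefully.
    """

    def __init__(self, message: str, fallback: str | None = None):
        if fallback is not None:
            message = f"{message} (nearest applicable fallback model: {fallback})"
        super().__init__(message)
        self.fallback = fallback


class ValidationError(AllomassError, ValueError):
    """A measurement or argument violates a domain precondition (e.g. length <= 0)."""


class UsageError(AllomassError, ValueError):
    """The operation was called in a way its contract forbids."""


class FittingError(AllomassError):
    """Model fitting failed, typically a rank-deficient or undersized grouping level."""


class FormatError(AllomassError, ValueError):
    """A data file does not conform to the declared CSV dialect."""
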