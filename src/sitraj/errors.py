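"""Exception hierarchy shared across the package.

Every precondition violation raises a subclass of :class:`SitrajError` so
callers can distinguish bad inputs from genuine bugs.  Error messages name
the offending field or quantity.
"""


class SitrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SitrajError, ValueError):
    """A configuration value is missing, malformed, or inconsistent."""


class InputError(SitrajError, ValueError):
    """Input data violate a documented contract (mixed users, unsorted dates...)."""


class SampleSizeError(SitrajError, ValueError):
    """Too few observations for the requested computation."""


class SingularDesignError(SitrajError, ValueError):
    """Design matrix is rank deficient (collinear or constant predictors)."""


class DegenerateOutcomeError(SitrajError, ValueError):
    """Outcome has zero variance; slopes/tests are undefined."""


class ClassError(SitrajError, ValueError):
    """A two-class computation received fewer than two classes."""


class InsufficientHistoryError(SitrajError, ValueError):
    """Not enough historical days/posts to train or window."""


class PredictionUnavailableError(SitrajError, ValueError):
    """No ensemble window has complete lag coverage for the target day."""


class DegenerateExtremesError(SitrajError, ValueError):
    """Extreme-percentile sets are indistinguishable (zero score spread)."""


class TokenizationError(SitrajError, ValueError):
    """Tokenization produced an empty vocabulary."""


class PairingError(SitrajError, ValueError):
    """An event lacks the trained per-user model it must be paired with."""


class WindowError(SitrajError, ValueError):
    """An alignment or comparison window contains no usable data."""


class FittingError(SitrajError, ValueError):
    """A model could not be fit on the provided training data."""
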