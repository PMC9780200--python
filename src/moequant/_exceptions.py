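"""Exception types shared across the package.

All of these subclass :class:`ValueError` (or :class:`KeyError` where a
lookup failed) so that callers who do not care about the fine distinction
can catch the built-in.
"""


class ValidationError(ValueError):
    """An input violated a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file was readable but not in the expected on-disk layout."""


class DomainError(ValueError):
    """A computation was requested outside its mathematical domain
    (empty mask, zero kept events, nonpositive control MFI, ...)."""


class DegenerateVarianceError(DomainError):
    """Both samples of a t-test carry zero variance; the statistic is
    undefined."""


class UndefinedFractionError(DomainError):
    """Both background-corrected region signals are zero; the in-Golgi
    fraction is 0/0."""


class PlacementError(RuntimeError):
    """Synthetic cells could not be placed without overlap; use fewer or
    smaller cells, or a larger field."""
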