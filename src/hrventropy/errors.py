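"""Exception hierarchy for hrventropy.

Every error raised by the library derives from :class:`HRVEntropyError`
so callers can catch the whole family with one clause.
"""


class HRVEntropyError(Exception):
    """Base class for all hrventropy errors."""


class InvalidInputError(HRVEntropyError, ValueError):
    """Input violates a precondition (length, finiteness, parameter range)."""


class UndefinedEntropyError(HRVEntropyError):
    """Sample entropy is undefined because one of the match averages is zero.

    Carries the offending ``phi_m`` and ``phi_m1`` values so callers can
    inspect how the computation degenerated instead of receiving a silent
    infinity.
    """

    def __init__(self, phi_m: float, phi_m1: float, message: str | None = None):
        self.phi_m = phi_m
        self.phi_m1 = phi_m1
        if message is None:
            message = (
                f"sample entropy undefined: phi_m={phi_m:g}, phi_m1={phi_m1:g} "
                "(no template matches at one of the lengths)"
            )
        super().__init__(message)


class DegenerateThresholdError(HRVEntropyError, ValueError):
    """A similarity threshold resolved to a non-positive value."""


class RRIParseError(HRVEntropyError, ValueError):
    """An RR-interval file contained a token that could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message)


class EmptyRecordError(HRVEntropyError, ValueError):
    """All intervals of a record were removed or the file was empty."""


class InsufficientLengthError(HRVEntropyError, ValueError):
    """A record is shorter than the requested analysis length."""


class DegenerateSampleError(HRVEntropyError, ValueError):
    """A statistical sample is constant or otherwise unusable."""


class InsufficientSampleError(HRVEntropyError, ValueError):
    """Too few non-missing values for a statistical comparison."""


class PlanError(HRVEntropyError, ValueError):
    """A sweep plan failed validation."""
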