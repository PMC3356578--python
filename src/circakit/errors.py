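"""Exception hierarchy shared across the package."""


class CircaKitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CircaKitError, ValueError):
    """A configuration or parameter violates its invariants."""


class OutOfRangeError(CircaKitError, ValueError):
    """A time falls outside the timeline covered by a schedule."""


class UndefinedZTError(CircaKitError, ValueError):
    """Zeitgeber Time was requested where no light-dark reference exists."""


class FormatError(CircaKitError, ValueError):
    """An input file does not conform to the declared dialect."""


class ZeroVarianceError(CircaKitError, ValueError):
    """A statistic is undefined because the input series is constant."""


class InsufficientDataError(CircaKitError, ValueError):
    """Not enough usable days/epochs/onsets for the requested estimate."""
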