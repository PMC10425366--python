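"""Exception hierarchy shared across the package.

All fearframe errors derive from :class:`FearframeError` so callers can
distinguish validation problems from genuine runtime failures.
"""


class FearframeError(Exception):
    """Base class for all package-specific errors."""


class TraceParseError(FearframeError):
    """The tracking export could not be parsed (bad columns, non-monotonic time)."""


class TraceValidationError(FearframeError):
    """A parsed trace violates a physical invariant (e.g. negative velocity)."""


class DataQualityError(FearframeError):
    """Trace has a dropout too long to interpolate safely."""


class DesignError(FearframeError):
    """A session design is internally inconsistent (overlapping CS windows, ...)."""


class EpochingError(FearframeError):
    """A trace is incompatible with the session design it is epoched against."""


class QuantificationError(FearframeError):
    """An image-quantification precondition failed (empty shell, bad ROI, ...)."""


class SimulationError(FearframeError):
    """A synthetic generator could not satisfy its placement constraints."""
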