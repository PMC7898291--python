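"""Exception hierarchy for soildoc.

All errors raised deliberately by the package derive from :class:`SoilDocError`
so callers can catch model errors separately from programming errors.
"""


class SoilDocError(Exception):
    """Base class for all soildoc errors."""


class InvalidInputError(SoilDocError, ValueError):
    """A physically meaningless input (negative stock, out-of-range fraction...)."""


class ConfigurationError(SoilDocError, ValueError):
    """An inconsistent parameter configuration (e.g. wilting >= optimum)."""


class DegenerateWaterStateError(SoilDocError, ValueError):
    """A concentration or leaching flux was requested with no water present."""


class ForcingError(SoilDocError, ValueError):
    """A forcing series violates its contract (gaps, NaNs, negative drivers)."""


class ConvergenceError(SoilDocError, RuntimeError):
    """Spin-up failed to reach the requested tolerance within max cycles."""


class MisalignedSeriesError(SoilDocError, ValueError):
    """State and flux series passed together do not share a time axis."""
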