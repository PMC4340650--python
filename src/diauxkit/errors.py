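"""Exception hierarchy shared across the toolkit."""


class DiauxkitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(DiauxkitError, ValueError):
    """A supplied parameter violates its domain (e.g. nonpositive factor)."""


class PlateFormatError(DiauxkitError, ValueError):
    """A plate-reader table does not conform to the long-format schema."""


class WindowError(DiauxkitError, ValueError):
    """A regression or averaging window holds too few usable points."""


class ShiftUnresolvedError(DiauxkitError, ValueError):
    """Growth never recovered above threshold after the arrest; the culture
    apparently entered stationary phase before resuming growth."""


class DegenerateDataError(DiauxkitError, ValueError):
    """Input data carry no usable variance for the requested statistic."""
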