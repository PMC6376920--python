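"""Exception hierarchy shared across the pipeline stages."""


class WinefpError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(WinefpError):
    """A tabular input could not be parsed; message names the offending line."""


class ConflictError(WinefpError):
    """Duplicate samples carry contradictory calls."""


class UsageError(WinefpError):
    """An operation was invoked with arguments outside its contract."""


class DomainError(WinefpError):
    """A numeric argument lies outside the mathematical domain of the operation."""


class BinError(WinefpError):
    """A peak size falls outside the locus plausibility window after calibration."""


class DegenerateFitError(WinefpError):
    """Too few usable bootstrap scales to fit the multiscale model."""
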