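"""Exception hierarchy for stpdosim.

All package-specific failures derive from :class:`StpdosimError` so callers
can catch one base class at pipeline level while tests discriminate on the
specific subtype.
"""


class StpdosimError(Exception):
    """Base class for all stpdosim errors."""


class InsufficientDataError(StpdosimError):
    """Raised when a time-activity curve has too few distinct time points to fit."""


class NonPhysicalKineticsError(StpdosimError):
    """Raised when a fit implies non-decreasing activity (lambda <= 0).

    All downstream time-integrated-activity formulas assume washout, so a
    non-positive decay coefficient is rejected rather than clamped.
    """


class ConfigError(StpdosimError):
    """Raised for invalid calibration, dosimetry or cohort configuration."""


class AggregationError(StpdosimError):
    """Raised when records that must share a patient/kidney do not."""


class InputError(StpdosimError):
    """Raised for malformed tabular input; the message names the offending row."""


class ScheduleWarning(UserWarning):
    """Warned when an imaging schedule deviates from the expected windows."""
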