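"""Exception hierarchy for panel ingest and metric computation."""


class HmisqaError(Exception):
    """Base class for all package errors."""


class PanelParseError(HmisqaError):
    """A file row could not be interpreted (names the offending row)."""


class PanelIntegrityError(HmisqaError):
    """A structural invariant is violated: duplicate keys, negative counts,
    month index out of range, or a registry link to an absent indicator."""


class UndefinedDenominatorError(HmisqaError):
    """An indicator has no non-missing value in any month, so the
    expected-units denominator (max monthly reporters) is undefined."""


class UndefinedRatioError(HmisqaError):
    """The anchor total of a consistency ratio is zero."""


class ConfigError(HmisqaError):
    """An invalid configuration value (probability out of range, empty
    period, infeasible generator setting)."""
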