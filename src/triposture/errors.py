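"""Exception hierarchy for the tri-monitor posture pipeline."""


class TripostureError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TripostureError):
    """An input file violates its declared tabular format."""


class DialectError(FormatError):
    """A declared column or code is missing from the file dialect."""


class EmptyInputError(FormatError):
    """An input file contains no data rows."""


class CountRangeError(TripostureError):
    """A raw ADC count lies outside the device version's count range."""


class ConfigurationError(TripostureError):
    """Mutually inconsistent or infeasible configuration values."""


class AlignmentError(TripostureError):
    """Monitor traces cannot be placed on a common sample clock."""


class InputTooShortError(TripostureError):
    """A trace is shorter than the filter warm-up requires."""


class CoverageError(TripostureError):
    """A bout falls (partly) outside the span of the aligned traces."""


class MissingDiaryError(TripostureError):
    """Events reference a calendar day absent from the sleep diary."""


class ConsistencyError(TripostureError):
    """Internal cross-references (sample -> bout) are broken."""


class EmptySummaryError(TripostureError):
    """No valid days available for per-day summarising."""
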