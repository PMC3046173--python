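"""Exception hierarchy for the hrvrisk pipeline."""


class HRVError(Exception):
    """Base class for all hrvrisk errors."""


class ParseError(HRVError):
    """A signal file contains a line that cannot be parsed."""


class EmptyInputError(HRVError):
    """An input file or series is empty."""


class ValidationError(HRVError):
    """Input values violate a domain contract (e.g. nonpositive intervals)."""


class InsufficientDataError(HRVError):
    """A series is too short for the requested computation."""


class ConfigurationError(HRVError):
    """A parameter is outside its allowed range."""


class SchemaError(HRVError):
    """Feature tables have inconsistent columns or dimensions."""


class LabelingError(HRVError):
    """Class labels are missing or degenerate (single class)."""


class NumericalError(HRVError):
    """A numerical procedure failed (singular system, non-finite values)."""
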