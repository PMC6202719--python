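"""Exception hierarchy for railmix."""


class RailmixError(Exception):
    """Base class for all railmix errors."""


class ParameterError(RailmixError, ValueError):
    """Invalid parameter value (out-of-range threshold, bad design, ...)."""


class DataError(RailmixError, ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Sequences that should share a coordinate frame do not."""
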