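"""Exception hierarchy for the NPD analysis pipeline.

Every rejected input maps to a distinct error class so callers (and the CLI)
can report *why* a tracing or cohort was refused rather than a bare ValueError.
"""


class NpdError(Exception):
    """Base class for all npdkit errors."""


class FormatError(NpdError):
    """A file does not have the expected structure (missing columns, bad header)."""


class DataError(NpdError):
    """Well-formed file whose values violate a data invariant
    (non-increasing time, unknown phase or group label, duplicate keys)."""


class ProtocolError(NpdError):
    """A tracing lacks a required perfusion phase or phases are out of protocol order."""


class StabilityError(NpdError):
    """No end-of-phase window satisfies the plateau stability rule;
    the tracing is flagged non-analyzable."""


class UndefinedScoreError(NpdError):
    """A diagnostic score is undefined for the given parameters
    (Wilschanski index with non-positive amiloride response)."""

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class ParameterError(NpdError):
    """A configuration parameter is out of its valid range."""


class InsufficientDataError(NpdError):
    """Too few observations for the requested statistic."""
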