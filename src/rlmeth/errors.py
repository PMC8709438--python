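"""Exception hierarchy.

``InputError`` marks problems with user-supplied files or configuration
(CLI exit code 2); ``AnalysisError`` marks conditions where a requested
quantity is undefined or a computation cannot proceed (CLI exit code 1).
"""


class RlmethError(Exception):
    """Base class for all package errors."""


class InputError(RlmethError):
    """Malformed or missing input data / configuration."""


class AnalysisError(RlmethError):
    """A computation is undefined or inconsistent for the given data."""
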