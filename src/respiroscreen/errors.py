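"""Exception hierarchy.

ValidationError maps to CLI exit code 1 (bad parameters / config),
DataError to exit code 2 (malformed or inconsistent input data).
"""


class RespiroscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(RespiroscreenError):
    """Invalid parameters, configuration or preconditions."""


class DataError(RespiroscreenError):
    """Malformed, inconsistent or missing input data."""
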