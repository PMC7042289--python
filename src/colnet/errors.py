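"""Exception types shared across the package."""


class ColnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ColnetError):
    """A configuration object or file is invalid or incomplete."""


class RecordRejectedError(ColnetError):
    """One or more records violate a model precondition.

    Carries the offending record ids so callers can locate the rows.
    """

    def __init__(self, message: str, record_ids=()):
        super().__init__(message)
        self.record_ids = list(record_ids)


class NameRejectedError(ColnetError):
    """A collector-name token could not be normalized."""

    def __init__(self, token: str, reason: str):
        super().__init__(f"rejected name token {token!r}: {reason}")
        self.token = token
        self.reason = reason
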