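"""Exception hierarchy.

``ValidationError`` covers bad configuration or malformed inputs detected up
front; ``RecordError`` carries the id(s) of the offending record(s) so a
pipeline failure names what broke.
"""


class DarkfixError(Exception):
    """Base class for all package errors."""


class ValidationError(DarkfixError):
    """Invalid configuration or input that fails a contract precondition."""


class RecordError(DarkfixError):
    """A record-level problem; ``ids`` names the offending records."""

    def __init__(self, message: str, ids=None):
        super().__init__(message)
        self.ids = list(ids) if ids is not None else []
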