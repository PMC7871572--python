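"""Exception hierarchy for comhub."""


class ComHubError(Exception):
    """Base class for all comhub errors."""


class ValidationError(ComHubError):
    """An input object or file violates a structural invariant."""


class ParseError(ComHubError):
    """A file could not be parsed; the message carries coordinates."""


class DegenerateDataError(ComHubError):
    """A computation is undefined on the given data (e.g. constant vectors)."""
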