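"""Exception types shared across the toolkit."""


class CbekitError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgument(CbekitError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(CbekitError, ValueError):
    """An input file violates its format contract (names the offending record)."""


class NotApplicable(CbekitError):
    """The requested quantity is undefined for this input (e.g. no codon annotation)."""
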