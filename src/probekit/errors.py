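"""Exception hierarchy."""


class ProbekitError(Exception):
    """Base class for all package errors."""


class FormatError(ProbekitError):
    """A CEL/CDF/TSV file violates the expected dialect."""


class EstimationError(ProbekitError):
    """A model parameter cannot be estimated from the given data."""


class AtmError(ProbekitError):
    """Threshold mapping failed (degenerate curve or partition)."""
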