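"""Exception types shared across the package."""


class PepscreenError(Exception):
    """Base class for all pepscreen errors."""


class FormatError(PepscreenError, ValueError):
    """A file or table does not conform to the expected layout."""


class ValidationError(PepscreenError, ValueError):
    """Input data violates a domain invariant (bad residue, bad range, ...)."""
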