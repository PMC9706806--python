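"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FitError(RuntimeError):
    """A model fit failed (degenerate or non-saturating data)."""


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""
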