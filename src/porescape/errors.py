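"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""
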