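"""Exception types mapped onto CLI exit codes (input error -> 2, numerical -> 3)."""


class InputError(ValueError):
    """Malformed, inconsistent, or missing input data or configuration."""


class NumericalError(RuntimeError):
    """A computation is degenerate or failed to produce a usable result."""
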