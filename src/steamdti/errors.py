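"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented invariant; the message names the field."""


class DegenerateNoiseError(ValidationError):
    """Noise SD estimated as zero (identical reference volumes)."""
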