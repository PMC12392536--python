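"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration file could not be parsed."""


class ValidationError(ValueError):
    """A parameter value violates its invariant. Carries the field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FitError(ValueError):
    """A distribution could not be fitted to the requested moments."""
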