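"""Exception types distinguishing bad configuration from bad data."""


class ConfigurationError(ValueError):
    """A hyperparameter or structural setting is inconsistent."""


class ValidationError(ValueError):
    """An input array or file violates a documented precondition."""
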