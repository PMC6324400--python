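"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A panel, synthetic-cohort or run configuration is invalid."""


class InputDataError(ValueError):
    """An input table violates the documented schema or invariants."""
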