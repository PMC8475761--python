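"""Exception types shared across the pipeline."""


class MontageError(ValueError):
    """A required channel is missing or the montage is inconsistent."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or degenerate."""


class StateError(ValueError):
    """An operation was applied to a tensor in the wrong transform state."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested for a constant vector."""
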