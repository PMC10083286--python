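"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument violates an operation's preconditions (bad fraction,
    malformed motif, flank unusable for anchoring, ...)."""


class ConfigError(ParameterError):
    """A run configuration is malformed or internally inconsistent."""


class DataError(RuntimeError):
    """Input data cannot be used (missing file, non-DNA sequence, ...)."""
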