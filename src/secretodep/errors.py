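"""Exception hierarchy shared across the pipeline stages."""


class SecretoDepError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SecretoDepError):
    """A table or annotation file violates its format contract."""


class DesignError(SecretoDepError):
    """Sample design is inconsistent (pairing, groups, cross-references)."""


class ConfigurationError(SecretoDepError):
    """A stage was configured with invalid parameters."""


class NormalizationError(SecretoDepError):
    """Spike-in normalization cannot proceed (missing or zero spike signal)."""
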