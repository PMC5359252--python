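"""Exception hierarchy for latentconn."""


class LatentConnError(Exception):
    """Base class for all latentconn errors."""


class ConfigurationError(LatentConnError):
    """An invalid generator / detection / inference configuration."""


class ValidationError(LatentConnError):
    """Input data violate a structural requirement (shape, symmetry, finiteness)."""
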