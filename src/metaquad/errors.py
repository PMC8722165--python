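"""Exception hierarchy shared by all metaquad modules."""


class MetaquadError(Exception):
    """Base class for all errors raised by metaquad."""


class FormatError(MetaquadError, ValueError):
    """An on-disk artifact is malformed (wrong field count, non-numeric cell, ...)."""


class ValidationError(MetaquadError, ValueError):
    """Parsed data violates a domain invariant (duplicate ids, bad event codes, ...)."""


class ConfigError(MetaquadError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class ConvergenceError(MetaquadError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""
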