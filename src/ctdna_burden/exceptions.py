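"""Exception hierarchy for the ctdna_burden pipeline."""


class CtdnaBurdenError(Exception):
    """Base class for all package errors."""


class DomainError(CtdnaBurdenError, ValueError):
    """An input violates a mathematical or clinical precondition."""


class SchemaError(CtdnaBurdenError, ValueError):
    """A table is missing required columns or contains inconsistent rows."""


class ConfigurationError(CtdnaBurdenError, ValueError):
    """A configuration field is out of its documented domain."""


class ConvergenceError(CtdnaBurdenError, RuntimeError):
    """A model fit failed to converge (e.g. separation in a Cox fit)."""
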