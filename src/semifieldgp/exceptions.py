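"""Exception hierarchy shared across the package."""


class SemifieldError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SemifieldError):
    """A configuration value is invalid (non-positive dimension, bad range)."""


class StructureError(SemifieldError):
    """A structural precondition is violated (padding, kernel shape, PSD)."""


class ValidationError(SemifieldError):
    """Input data fail a validation rule."""


class DegenerateInputError(SemifieldError):
    """The computation is undefined on this input (all-monomorphic SNPs, zero variance)."""


class ConvergenceError(SemifieldError):
    """An iterative solver failed and the failure cannot be represented as a flagged result."""
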