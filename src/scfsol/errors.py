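"""Exception hierarchy shared across the package."""


class ScfsolError(Exception):
    """Base class for all package errors."""


class DomainError(ScfsolError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class FormatError(ScfsolError, ValueError):
    """A file or record does not match the expected schema."""


class ValidationError(ScfsolError, ValueError):
    """A dataset or record violates a declared invariant."""


class ConfigError(ScfsolError, ValueError):
    """An unknown identifier or inconsistent configuration block."""


class NonphysicalStateError(ScfsolError, ValueError):
    """No equation-of-state root with molar volume above the co-volume."""


class ConvergenceError(ScfsolError, RuntimeError):
    """Iterative solver exhausted its budget without meeting tolerance."""


class UnderdeterminedError(ScfsolError, ValueError):
    """Fewer data points than free coefficients."""


class FitError(ScfsolError, RuntimeError):
    """Every optimizer start failed for a regression problem."""
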