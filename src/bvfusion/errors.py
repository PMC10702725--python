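"""Exception hierarchy shared across the pipeline."""


class BvFusionError(Exception):
    """Base class for all package errors."""


class InputError(BvFusionError, ValueError):
    """Invalid data passed to an operation (shape, finiteness, class balance)."""


class ConfigurationError(BvFusionError, ValueError):
    """Invalid configuration value (unknown mode, empty band, bad grid)."""


class NumericError(BvFusionError, ArithmeticError):
    """A numerical procedure failed (non-convergence, singular matrix, divergence)."""


class StateError(BvFusionError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unfitted model)."""
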