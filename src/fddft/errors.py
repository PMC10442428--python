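"""Exception hierarchy for the fddft pipeline.

Every stage raises a named subclass of :class:`FddftError` so callers can
attach stage context without string-matching messages.
"""


class FddftError(Exception):
    """Base class for all package errors."""


class NonFiniteInputError(FddftError, ValueError):
    """Input contains NaN or infinite entries."""


class EmptyForegroundError(FddftError, ValueError):
    """No pixel exceeds the foreground threshold."""


class ImageReadError(FddftError, IOError):
    """A 2-D image file could not be read or has an unsupported layout."""


class VolumeReadError(FddftError, IOError):
    """A volume file could not be read or has mismatched dimensions."""


class KernelDimensionError(FddftError, ValueError):
    """Reciprocal distance kernel dimensions must be integers >= 2."""


class FactorRangeError(FddftError, ValueError):
    """Dimension-reduction factor outside (0, 1]."""


class ZeroKineticError(FddftError, ValueError):
    """Adaptive scaling factor undefined: mean kinetic energy is zero."""


class ConstantInputError(FddftError, ValueError):
    """Fermi normalization undefined: input matrix is constant (sigma = 0)."""


class StabilizationError(FddftError, RuntimeError):
    """Gradient ascent failed to reach <L> >= 0 within the iteration cap."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = list(trace)


class ShapeMismatchError(FddftError, ValueError):
    """Arrays that must share a shape do not."""


class PhantomSpecError(FddftError, ValueError):
    """Phantom specification is geometrically invalid."""
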