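"""Exception hierarchy."""


class PowderChainError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(PowderChainError, ValueError):
    """Invalid geometry or detector description."""


class UnreachableReflection(PowderChainError, ValueError):
    """Bragg condition cannot be satisfied, or the ring does not close on the detector."""


class DegenerateConic(PowderChainError, ValueError):
    """Point set does not determine an ellipse (collinear, or best conic not an ellipse)."""


class CalibrantError(PowderChainError, ValueError):
    """Unknown calibrant name or invalid line list."""


class RingFindError(PowderChainError, RuntimeError):
    """Ring location failed (no rings detected, too few accepted profile fits, ...)."""


class CalibrationError(PowderChainError, RuntimeError):
    """Geometry refinement failed to produce a usable solution."""


class SingularCalibration(CalibrationError):
    """The normal matrix is (near-)singular for the chosen free-parameter set.

    Carries the names of the most strongly coupled parameters, e.g. the classic
    distance–wavelength degeneracy when only low-angle rings are available.
    """

    def __init__(self, message, parameters=()):
        super().__init__(message)
        self.parameters = tuple(parameters)


class ReductionError(PowderChainError, RuntimeError):
    """A per-frame reduction step cannot produce output (e.g. everything masked)."""


class ChainError(PowderChainError, ValueError):
    """Invalid chain definition: unknown step, schema violation, kind mismatch."""


class FileFormatError(PowderChainError, RuntimeError):
    """Malformed or unsupported input/output file."""
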