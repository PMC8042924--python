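"""Exception hierarchy shared across the package."""


class RufflekitError(Exception):
    """Base class for all rufflekit errors."""


class InvalidParameterError(RufflekitError, ValueError):
    """A parameter violates its documented domain."""


class InsufficientDataError(RufflekitError, ValueError):
    """Too few observations to run the requested analysis."""


class FitFailureError(RufflekitError, RuntimeError):
    """Optimizer failed to converge from every starting point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DomainError(RufflekitError, ValueError):
    """Inputs are individually valid but jointly outside the formula's domain."""


class OutOfBoundsError(RufflekitError, ValueError):
    """A geometry does not fit inside the rendering volume."""


class SceneTooCrowdedError(RufflekitError, RuntimeError):
    """Rejection sampling could not place all ruffles without overlap."""


class UnmeasurableProfileError(RufflekitError, ValueError):
    """An intensity profile has no well-defined full width at half maximum."""


class InvalidROIError(RufflekitError, ValueError):
    """Regions of interest violate the equal-size / disjointness contract."""


class UndefinedRatioError(RufflekitError, ValueError):
    """Cytosol reference intensity does not exceed the camera offset."""
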