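"""Exception hierarchy for the characterization pipeline."""


class PhonescopeError(Exception):
    """Base class for all pipeline errors."""


class DegenerateSceneError(PhonescopeError):
    """Scene geometry cannot host the requested target (e.g. image smaller
    than one grid period)."""


class GeometryError(PhonescopeError):
    """A requested coordinate / segment / window lies outside the image."""


class InsufficientStructureError(PhonescopeError):
    """Too few lines or grid intersections detected to estimate geometry."""


class FitError(PhonescopeError):
    """Nonlinear fit failed to converge or the data offer fewer extrema than
    requested peaks.  Carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
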