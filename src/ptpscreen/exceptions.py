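"""Exception hierarchy for assay, kinetics and regression failures."""


class PTPScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PTPScreenError, ValueError):
    """A physical parameter violates its domain (e.g. non-positive Km)."""


class DegenerateControlError(PTPScreenError, ValueError):
    """Control absorbance change is non-positive; inhibition rate undefined."""


class MixedDoseError(PTPScreenError, ValueError):
    """A screening panel mixes doses without the override flag."""


class InsufficientDataError(PTPScreenError, ValueError):
    """Too few usable observations to fit."""


class NoFitError(PTPScreenError, ValueError):
    """Regression is degenerate (flat or wrong-signed slope)."""


class InconsistentKineticsError(PTPScreenError, ValueError):
    """Secondary-replot geometry implies a negative inhibition constant."""


class ComponentCollapseError(PTPScreenError, ValueError):
    """NIPALS deflation exhausted the data before the requested rank."""

    def __init__(self, message: str, achieved_rank: int):
        super().__init__(message)
        self.achieved_rank = achieved_rank


class ColumnMismatchError(PTPScreenError, ValueError):
    """Prediction matrix columns do not match the fitted model."""
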