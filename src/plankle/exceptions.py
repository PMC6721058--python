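"""Package-level exception hierarchy."""


class PlankleError(Exception):
    """Base class for all errors raised by plankle."""


class DegenerateGeometryError(PlankleError, ValueError):
    """Geometry with no well-defined direction (coincident endpoints,
    coincident sphere centers with a projection requested, ...)."""


class NumericalError(PlankleError, ArithmeticError):
    """A numerical quantity became NaN during a solve."""


class UnfittableProblemError(PlankleError, ValueError):
    """A fine-tuning problem in which no displacement activates the planar
    cable, leaving the material parameters unidentifiable."""
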