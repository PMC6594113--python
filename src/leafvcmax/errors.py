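"""Exception hierarchy shared across the package."""


class LeafModelError(Exception):
    """Base class for all leafvcmax errors."""


class GridError(LeafModelError):
    """Wavelength grids do not match or do not cover the required range."""


class DomainError(LeafModelError, ValueError):
    """A parameter or input is outside its physical domain."""


class DataError(LeafModelError):
    """Measured data are missing, malformed or physically impossible."""


class InsufficientDataError(DataError):
    """Too few valid points to attempt a fit."""


class ConvergenceError(LeafModelError):
    """An iterative solver failed to converge.

    Carries a ``diagnostics`` dict (last iterate, residual, iteration count)
    to help track down the offending forcing/parameter combination.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
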