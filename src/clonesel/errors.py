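"""Exception types shared across the package."""


class ClonalSelectionError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ClonalSelectionError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ShapeError(ClonalSelectionError, ValueError):
    """Array arguments have inconsistent lengths or shapes."""


class IntegrationError(ClonalSelectionError, RuntimeError):
    """The adaptive time integrator failed to meet its tolerances.

    Attributes
    ----------
    last_time : float
        Last time point accepted by the solver before the failure.
    """

    def __init__(self, message: str, last_time: float = float("nan")):
        super().__init__(message)
        self.last_time = last_time


class BracketingError(ClonalSelectionError, ValueError):
    """A bisection bracket does not contain a sign change / classification flip."""


class InsufficientInformationError(ClonalSelectionError, ValueError):
    """A prediction needs structural information (e.g. local Taylor orders)
    that the profile does not carry."""
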