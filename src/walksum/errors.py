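"""Named failure modes.

Every validation failure raises a distinct class so callers can react to
(or test for) the specific problem rather than parsing messages.
"""


class WalksumError(Exception):
    """Base class for all package-specific errors."""


class DimensionMismatchError(WalksumError, ValueError):
    """Matrices that must share a shape do not."""


class NegativeEntryError(WalksumError, ValueError):
    """A weight or distance matrix contains negative entries."""


class NonFiniteError(WalksumError, ValueError):
    """A matrix or series contains NaN or infinite entries."""


class AsymmetryError(WalksumError, ValueError):
    """An undirected connectome was given an asymmetric matrix."""


class ConvergenceError(WalksumError, ValueError):
    """The walk series does not converge (spectral radius >= 1)."""


class SingularFrequencyError(WalksumError, ValueError):
    """The resolvent system is singular at a specific frequency."""

    def __init__(self, frequency_hz: float, message: str | None = None):
        self.frequency_hz = frequency_hz
        super().__init__(
            message or f"resolvent system singular at {frequency_hz:g} Hz"
        )


class IsolatedNodeError(WalksumError, ValueError):
    """A node with zero degree breaks a degree-normalised operation."""


class BandCoverageError(WalksumError, ValueError):
    """The frequency grid does not cover a required band."""


class BinningError(WalksumError, ValueError):
    """Distance binning is impossible or incompatible."""


class EstimatorError(WalksumError, ValueError):
    """A spectral estimator precondition is violated."""


class SimulationError(WalksumError, RuntimeError):
    """A neural-mass integration failed (non-finite state)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at integration step {step}")
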