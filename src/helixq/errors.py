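"""Exception hierarchy shared across the package."""


class HelixQError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HelixQError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidGridError(HelixQError, ValueError):
    """A discretization grid violates a resolution contract."""


class SolverFailureError(HelixQError, RuntimeError):
    """Nonlinear solver failed to converge.

    Carries the residual history of the attempted iteration.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class MatchingFailureError(HelixQError, RuntimeError):
    """Far-field amplitude matching dispersion exceeded its tolerance."""


class SurfaceBuildError(HelixQError, RuntimeError):
    """A node solve failed while tabulating an effective-charge surface."""


class InsufficientDataError(HelixQError, ValueError):
    """Too few events for a statistical estimate."""


class DegenerateDataError(HelixQError, ValueError):
    """Data admit no valid estimate (e.g. non-positive mean dwell time)."""


class InvalidThresholdError(HelixQError, ValueError):
    """Event-detection threshold lies outside the trace intensity range."""


class InvalidTimestepError(HelixQError, ValueError):
    """Brownian-dynamics timestep violates the step-size contract."""


class DegenerateMeasurementError(HelixQError, ValueError):
    """Measured charge indistinguishable from the additive dye offset."""


class InconsistentDataError(HelixQError, RuntimeError):
    """Measurements incompatible with the model grid (all weights underflow)."""


class BoundarySolutionError(HelixQError, RuntimeError):
    """Posterior mode fell on the grid boundary; the grid must be widened."""


class DegenerateManifoldError(HelixQError, RuntimeError):
    """Manifold mode is ridge-like (underdetermined), e.g. from too few ratios."""


class SignInconsistencyError(HelixQError, RuntimeError):
    """Recovered multiplicative factor has an unphysical sign."""


class DegenerateDesignError(HelixQError, ValueError):
    """Regression design matrix is rank deficient."""


class DependencyError(HelixQError, FileNotFoundError):
    """A required upstream artifact (table, surface) is missing."""


class UnphysicalConfigurationError(HelixQError, ValueError):
    """Configuration implies a non-trapping (W <= 0) energy landscape."""


class InvalidFixtureError(HelixQError, ValueError):
    """Synthetic fixture request is internally inconsistent."""
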