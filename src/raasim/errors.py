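"""Exception hierarchy for raasim."""


class RaasimError(Exception):
    """Base class for all raasim errors."""


class ConfigurationError(RaasimError):
    """A configuration file or parameter override is invalid."""


class DomainError(RaasimError, ValueError):
    """An argument violates a rate law's physical domain (negative
    concentration, hematocrit >= 1, non-positive half-life, ...)."""


class ConvergenceError(RaasimError):
    """Steady-state construction failed to reach the residual tolerance."""


class SolverError(RaasimError):
    """The ODE integrator failed; carries the last successful time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time
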