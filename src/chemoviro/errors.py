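"""Exception hierarchy shared across the package."""


class ChemoviroError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ChemoviroError, ValueError):
    """A parameter value violates its admissibility constraints."""


class DomainError(ChemoviroError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class IntegrationFailure(ChemoviroError, RuntimeError):
    """The integrator produced NaN/Inf or an inadmissible state.

    Carries ``last_valid_time``, the last grid time with a finite,
    admissible state.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class RefinementFailure(ChemoviroError, RuntimeError):
    """Newton refinement of a steady-state candidate diverged or moved too far."""
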