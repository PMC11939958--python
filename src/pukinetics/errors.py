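"""Exception hierarchy shared by all pukinetics modules."""


class PuKineticsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PuKineticsError, ValueError):
    """A physical parameter violates its domain (sign, range, units)."""


class ConfigurationError(PuKineticsError, ValueError):
    """A configuration file, unit name, or model name is not recognised."""


class DataDomainError(PuKineticsError, ValueError):
    """Observed data lie outside the domain a fitter requires
    (e.g. non-positive masses for a log transform, coverage >= 1)."""


class UnidentifiableParametersError(PuKineticsError, ValueError):
    """The data carry no information about the requested parameters."""


class NumericalBlowupError(PuKineticsError, ArithmeticError):
    """The integrator produced a non-finite state.

    Carries the time at which the state first became non-finite.
    """

    def __init__(self, time: float, message: str | None = None):
        self.time = time
        super().__init__(message or f"non-finite state at t = {time} h")
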