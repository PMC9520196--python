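"""Exception hierarchy for soilcom."""


class SoilcomError(Exception):
    """Base class for all soilcom errors."""


class ParameterError(SoilcomError, ValueError):
    """A kinetic or model parameter violates its constraints."""


class ConfigError(SoilcomError, ValueError):
    """A configuration file or option is invalid."""


class SolverError(SoilcomError, RuntimeError):
    """The stiff integrator failed; carries generation index and state."""

    def __init__(self, message, generation=None, state=None):
        super().__init__(message)
        self.generation = generation
        self.state = state


class FitError(SoilcomError, RuntimeError):
    """A statistical fit failed to converge or the data are degenerate."""


class DiversityError(SoilcomError, ValueError):
    """Diversity is undefined (e.g. all-zero biomass vector)."""
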