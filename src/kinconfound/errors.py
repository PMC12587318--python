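"""Exception hierarchy shared by all pipeline stages."""


class KinconfoundError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KinconfoundError, ValueError):
    """A model or generator parameter is outside its admissible range."""


class ConfigurationError(KinconfoundError, ValueError):
    """A configuration table (periods, strata, ...) is malformed or incomplete."""


class ExtinctionError(KinconfoundError, RuntimeError):
    """The simulated population died out before the requested generation."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(
            f"population extinct at generation {generation}: "
            "fewer than one mateable couple remains"
        )


class EstimationError(KinconfoundError, ValueError):
    """Too little usable data for a correlation estimate."""


class FitError(KinconfoundError, ValueError):
    """Too few usable relationship-level estimates for a model fit."""


class DegeneracyError(KinconfoundError, ValueError):
    """A partial correlation is undefined (a conditioning correlation is +-1)."""


class NumericalError(KinconfoundError, RuntimeError):
    """A numerical routine (e.g. PSD projection) failed; carries diagnostics."""
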