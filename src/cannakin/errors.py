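"""Exception hierarchy.

Everything raised deliberately by cannakin derives from :class:`CannakinError`
so callers can catch the package's failures in one clause.  Subclasses also
derive from the closest builtin (ValueError, KeyError, ...) so that generic
handling keeps working.
"""


class CannakinError(Exception):
    """Base class for all cannakin errors."""


class InvalidArgumentError(CannakinError, ValueError):
    """A numeric argument violates a precondition (e.g. negative concentration)."""


class UnknownEnzymeError(CannakinError, KeyError):
    """A variant or lookup names an enzyme absent from the model."""


class UnknownSpeciesError(CannakinError, KeyError):
    """A species id is not part of the model or trajectory."""


class ConfigError(CannakinError, ValueError):
    """A scenario configuration contains an unknown or inconsistent key."""


class UnsupportedScenarioError(ConfigError):
    """The requested scenario (e.g. a native FAS route) is not modeled."""


class SolverError(CannakinError, RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class StabilityError(SolverError):
    """Integration produced a negative-concentration excursion beyond tolerance."""


class ContractError(CannakinError, ValueError):
    """A trajectory/model pair does not belong together."""


class UndefinedYieldError(CannakinError, ZeroDivisionError):
    """Yield requested over a run in which no substrate was consumed."""


class CalibrationFailedError(CannakinError, RuntimeError):
    """No calibration start converged below the configured objective ceiling."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UnsupportedRateLawError(CannakinError, ValueError):
    """An imported kinetic law is not one of the forms this package models."""


class SBMLReadError(CannakinError, ValueError):
    """An SBML document could not be parsed or fails schema consistency."""
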