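"""Exception hierarchy for the lipoprotein kinetics pipeline."""


class LipometError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LipometError, ValueError):
    """A kinetic parameter is non-positive or otherwise inadmissible."""


class DegenerateModelError(LipometError):
    """A size bin has zero total outflow rate but nonzero inflow, so no
    steady state exists."""


class UnfittableProfileError(LipometError, ValueError):
    """The observed profile carries too little information to fit
    (all-zero, or fewer than the minimum number of nonzero subclasses)."""


class ConvergenceError(LipometError):
    """No optimizer start converged.  Carries the best-effort parameters
    so callers can inspect them, flagged unreliable."""

    def __init__(self, message, parameters=None, diagnostics=None):
        super().__init__(message)
        self.parameters = parameters
        self.diagnostics = diagnostics


class UndefinedIndicatorError(LipometError, ZeroDivisionError):
    """An indicator's denominator flux is zero for this subject."""


class ConfigError(LipometError, ValueError):
    """A configuration value is missing, inconsistent, or out of range."""
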