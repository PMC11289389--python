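"""Exception hierarchy for amyloop."""


class AmyloopError(Exception):
    """Base class for all amyloop errors."""


class ConfigError(AmyloopError):
    """Invalid configuration: unknown key, bad value, or violated invariant."""


class InputError(AmyloopError):
    """Invalid input to a computational routine."""


class IntegrationError(AmyloopError):
    """ODE solver failed to converge.

    Attributes
    ----------
    failure_time : float or None
        Time (s) at which integration stopped, if known.
    """

    def __init__(self, message, failure_time=None):
        super().__init__(message)
        self.failure_time = failure_time


class DivergenceError(IntegrationError):
    """A concentration exceeded the 1 M blow-up bound during integration."""


class FitError(AmyloopError):
    """Curve fit failed or produced a non-physical result."""


class SteadyStateError(AmyloopError):
    """A steady state was requested where the dynamics are oscillatory."""


class SweepError(AmyloopError):
    """A parameter sweep failed at too many grid points."""
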