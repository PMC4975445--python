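"""Exception hierarchy.

Validation problems (bad parameters, bad configuration files) and numerical
problems (integrator failure, absent steady state) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class PeroxidynError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PeroxidynError, ValueError):
    """A kinetic constant, strain factor or population setting is invalid."""


class ConfigurationError(PeroxidynError, ValueError):
    """A configuration file or scenario definition failed validation."""


class UnsupportedRegimeError(PeroxidynError, ValueError):
    """Closed-form solutions were requested in the intermediate regime.

    Between roughly 10 and 30 uM external H2O2 neither the linear (Ahp
    unsaturated) nor the saturated approximation holds; callers must use
    the numerical simulator instead.
    """


class NoSteadyStateError(PeroxidynError, ArithmeticError):
    """Endogenous production exceeds total scavenging capacity."""


class SolverError(PeroxidynError, RuntimeError):
    """Stiff integration failed; carries the last valid state reached."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state
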