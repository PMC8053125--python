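"""Exception hierarchy shared across the package."""


class AptakineticsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AptakineticsError):
    """A scheme, rate set or option is inconsistent or incomplete."""


class InputError(AptakineticsError):
    """Malformed or physically invalid input data (CSV files, traces, grids)."""


class SimulationError(AptakineticsError):
    """The ODE integrator failed or produced unphysical concentrations."""


class FitConvergenceError(AptakineticsError):
    """No optimizer start converged to an acceptable solution."""
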