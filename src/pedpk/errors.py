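"""Exception hierarchy. Distinct classes map to distinct CLI exit codes."""


class PedpkError(Exception):
    """Base class for all package errors."""


class DomainError(PedpkError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ConfigError(PedpkError, ValueError):
    """A configuration file or override is invalid."""


class SolverError(PedpkError, RuntimeError):
    """The ODE integration failed."""


class ConvergenceError(PedpkError, RuntimeError):
    """A calibration stage failed to converge."""


class InfeasibleError(PedpkError, ValueError):
    """A requested calibration target cannot be met by any parameter value."""
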