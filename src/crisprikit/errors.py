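"""Exception hierarchy."""


class CrisprikitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrisprikitError):
    """A model, parameter set or config file is inconsistent or incomplete."""


class DomainError(CrisprikitError):
    """An input violates a mathematical precondition (e.g. negative state)."""


class CalibrationError(CrisprikitError):
    """A requested calibration target cannot be reached within the bracket."""


class SolverError(CrisprikitError):
    """A numerical routine failed to converge; message names the failure point."""


class EmptyEquilibriumSetError(SolverError):
    """Multistart root finding converged to no equilibrium at all."""
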