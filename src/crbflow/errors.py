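"""Exception hierarchy shared by all crbflow stages."""


class CRBFlowError(Exception):
    """Base class for all crbflow errors."""


class ConfigurationError(CRBFlowError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class InputError(CRBFlowError, ValueError):
    """Input data violate a precondition of an operation."""


class GatingError(CRBFlowError):
    """No events survived the DAPI gate; downstream fractions are undefined."""


class UndefinedStatisticError(CRBFlowError):
    """A statistic is undefined for the given input (zero mean, zero variance, ...)."""


class ConvergenceError(CRBFlowError):
    """An iterative fit failed to converge; carries the iteration count reached."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter
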