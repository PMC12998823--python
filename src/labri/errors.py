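"""Exception types shared across the package."""


class LabriError(Exception):
    """Base class for package errors."""


class DegenerateDataError(LabriError):
    """Input data carry no usable spread (constant vector, zero IQR, ...)."""


class InverseDomainError(LabriError):
    """A Box-Cox inverse was requested outside its domain (1 + lambda*y <= 0)."""


class EstimationError(LabriError):
    """The central-distribution estimator could not produce an accepted fit."""
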