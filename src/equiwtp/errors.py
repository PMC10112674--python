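"""Exception hierarchy shared across the package."""


class EquiwtpError(Exception):
    """Base class for all package errors."""


class ClassificationError(EquiwtpError):
    """Respondent cannot be assigned to owner/boarder/leaser."""


class DataError(EquiwtpError):
    """Malformed or internally inconsistent respondent data."""


class ConfigError(EquiwtpError):
    """Invalid simulation or estimation configuration."""


class EstimationError(EquiwtpError):
    """Estimation cannot proceed (unidentified model, rank deficiency, ...)."""


class NonConvergenceError(EstimationError):
    """Optimizer failed to reach the gradient tolerance."""
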