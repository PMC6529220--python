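"""Exception hierarchy for the visuo-haptic statistical learning package."""


class VisuoHapticError(Exception):
    """Base class for all package errors."""


class InvalidInventoryError(VisuoHapticError):
    """Inventory construction or shape mismatch errors."""


class MissingSeedError(VisuoHapticError):
    """A stochastic operation was called without an explicit seed."""


class InvalidSceneError(VisuoHapticError):
    """Scene construction violates a placement constraint."""


class UnsupportedSceneError(VisuoHapticError):
    """Operation defined only for 2x2 pull scenes received something else."""


class ConfigError(VisuoHapticError):
    """Invalid run or cohort configuration."""


class DataError(VisuoHapticError):
    """Malformed behavioral data (counts, lengths, schema)."""


class EmptyInputError(DataError):
    """An aggregation was asked for on an empty input."""


class InsufficientDataError(DataError):
    """Too few observations for the requested test."""


class IncompleteLogError(DataError):
    """A trial log is missing a phase required by an analysis."""


class DataMismatchError(DataError):
    """Two fits claimed to share data do not (fingerprint mismatch)."""


class NonConvergenceError(VisuoHapticError):
    """All optimizer starts failed."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NumericalCurvatureError(VisuoHapticError):
    """Hessian not positive definite where positive definiteness is required."""


class DegenerateBandError(VisuoHapticError):
    """No retained samples when building a confidence band."""


class IntegrationError(VisuoHapticError):
    """Numerical quadrature failed to converge."""
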