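"""Exception hierarchy for the pressure-curve and survival pipeline."""


class DiastolicaError(Exception):
    """Base class for all package errors."""


class ParameterError(DiastolicaError, ValueError):
    """Invalid parameter value or combination."""


class SegmentationError(DiastolicaError):
    """Cardiac-cycle segmentation failed (too few upstrokes detected)."""


class FiducialError(DiastolicaError):
    """Fiducial detection produced a non-physiologic configuration."""


class SelectionError(DiastolicaError):
    """Not enough cycles to select the requested end-expiration run."""


class DegenerateSplitError(DiastolicaError, ValueError):
    """Median dichotomization impossible: all values identical."""


class DegeneracyError(DiastolicaError):
    """Covariate matrix is degenerate (constant column, too few events)."""


class ConvergenceError(DiastolicaError):
    """Partial-likelihood maximization failed to converge."""


class BootstrapError(DiastolicaError):
    """Too many bootstrap resamples failed to yield the statistic."""


class ConcordanceError(DiastolicaError):
    """No usable pairs: the concordance index is undefined."""


class ValidationError(DiastolicaError, ValueError):
    """Input table failed schema validation."""
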