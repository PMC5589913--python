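"""Exception hierarchy for the pipeline."""


class EpiratchetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EpiratchetError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class DegenerateInterfaceError(InvalidInputError):
    """Zero-length interface where an orientation is required."""


class NoCellsError(EpiratchetError):
    """Segmentation produced no cells (e.g. a flat image)."""


class TrackingFailureError(EpiratchetError):
    """No frame-to-frame correspondence could be established."""


class InvalidLagError(InvalidInputError):
    """Requested MSD lag exceeds what the trajectory supports."""


class FitFailureError(EpiratchetError):
    """Least-squares fit failed to converge from every start point.

    Carries the per-start diagnostics in ``.diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class InvalidWindowError(InvalidInputError):
    """Degenerate or out-of-range time window."""


class InvalidIntervalError(InvalidInputError):
    """Compartment interval outside the measured series."""


class NumericDomainError(EpiratchetError):
    """A quantity left its mathematically valid domain (e.g. trend <= 0)."""


class InvalidJError(InvalidInputError):
    """Too many wavelet planes for the image size."""


class OutOfTissueError(EpiratchetError):
    """A detection centroid falls outside the segmented region."""


class ConfigError(EpiratchetError):
    """Invalid pipeline configuration."""


class ParameterError(InvalidInputError):
    """Synthetic-data parameters are infeasible."""
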