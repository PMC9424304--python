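"""Exception and warning types shared across the pipeline."""


class UVPlumeError(Exception):
    """Base class for all package errors."""


class DegenerateStimulus(UVPlumeError):
    """A spectrum produced zero quantum catch in every receptor."""


class LayoutError(UVPlumeError):
    """Specimen-image layout regions overlap or fall outside the canvas."""


class BoundsError(UVPlumeError):
    """Coordinates fall outside the image bounds."""


class EmptySegmentation(UVPlumeError):
    """A segmentation method produced no foreground pixels."""


class SeedError(UVPlumeError):
    """Region growing was given no usable seed points."""


class ShapeError(UVPlumeError):
    """Two masks being compared have different shapes."""


class UndefinedMetric(UVPlumeError):
    """A confusion-count ratio has a zero denominator."""


class StandardOrderError(UVPlumeError):
    """Grey-standard mean intensities are not increasing with nominal reflectance."""


class SingularFit(UVPlumeError):
    """The polynomial mapping design matrix is rank deficient."""


class TransformError(UVPlumeError):
    """A response transform (log10) hit non-positive values."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = [] if rows is None else list(rows)


class LabelError(UVPlumeError):
    """Tree tip labels and trait-table species do not match."""


class ChainError(UVPlumeError):
    """The Gibbs sampler produced a non-finite draw."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


class SpecError(UVPlumeError):
    """Posterior draw sets being pooled have mismatched parameters."""


class EmptyInput(UVPlumeError):
    """A metric was requested on an empty pixel set."""


class ShortSampleWarning(UserWarning):
    """Fewer aggregated cells than the requested sample size."""


class SeparationWarning(UserWarning):
    """A predictor perfectly separates a binary response."""
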