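"""Domain exceptions raised across the pipeline."""


class PPDScoreError(Exception):
    """Base class for all ppdscore errors."""


class ShapeError(PPDScoreError):
    """An image or mask has the wrong number of channels or mismatched shape."""


class InvalidImageError(PPDScoreError):
    """Pixel data is unusable (NaN values, intensities out of range)."""


class DegenerateRoiError(PPDScoreError):
    """No usable region of interest survives detection/erosion."""


class DegenerateSliceError(PPDScoreError):
    """The ROI is essentially black (upper quantile ~ 0): a photography
    failure, not evidence of zero deterioration."""


class MissingRootError(PPDScoreError):
    """A root has no scoreable slice."""


class MissingTimepointError(PPDScoreError):
    """A cultivar trajectory lacks a required assessment timepoint."""


class ClusteringError(PPDScoreError):
    """Invalid k-means inputs (k > n, duplicate cultivars, unfitted model)."""


class UndefinedCorrelationError(PPDScoreError):
    """Correlation requested on a zero-variance or too-short vector."""


class ModelSpecificationError(PPDScoreError):
    """Rank-deficient design or an ill-posed term-deletion request."""
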