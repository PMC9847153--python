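"""Grayscale PPD scoring of cassava root-slice photographs.

The deterioration of cassava storage roots after harvest (post-harvest
physiological deterioration, PPD) shows up in a photographed slice as dark
vascular streaking against the light parenchyma.  The score used here
summarises that contrast as the relative spread of grayscale intensities
inside a region of interest (ROI)::

    score = (Q97.5 - Q2.5) / Q97.5

where ``Q2.5`` and ``Q97.5`` are the 2.5% and 97.5% empirical quantiles of
the ROI pixel intensities.  A uniform, healthy slice scores near 0; heavy
streaking widens the intensity histogram and pushes the score toward 1.
The score is invariant to a multiplicative change of illumination.

Per root, the score is the arithmetic mean of the proximal, central and
distal slice scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .exceptions import (
    DegenerateRoiError,
    DegenerateSliceError,
    InvalidImageError,
    MissingRootError,
    ShapeError,
)

#: Luma weights of the standard RGB -> grayscale conversion (ITU-R BT.601),
#: the convention used by MATLAB's rgb2gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Lower/upper quantiles entering the score.
Q_LOW = 0.025
Q_HIGH = 0.975

#: Upper-quantile floor below which a slice is declared unusable.
EPS_Q_HIGH = 1e-6

#: Minimum ROI size (pixels) for a scoreable slice.
MIN_ROI_PIXELS = 100

SLICE_POSITIONS = ("proximal", "central", "distal")


@dataclass(frozen=True)
class RoiParams:
    """Parameters of automatic ROI detection.

    background_threshold_mode : "otsu" or "fixed"
    fixed_threshold : intensity in (0, 1), used in "fixed" mode
    peel_erosion_px : radius (px) of the binary erosion that strips the
        darker peel ring from the detected disc
    min_component_px : connected components smaller than this are discarded
    """

    background_threshold_mode: str = "otsu"
    fixed_threshold: float = 0.5
    peel_erosion_px: int = 10
    min_component_px: int = 256

    def __post_init__(self) -> None:
        if self.background_threshold_mode not in ("otsu", "fixed"):
            raise ValueError(
                f"unknown threshold mode {self.background_threshold_mode!r}"
            )
        if not 0.0 < self.fixed_threshold < 1.0:
            raise ValueError("fixed_threshold must lie in (0, 1)")
        if self.peel_erosion_px < 0:
            raise ValueError("peel_erosion_px must be >= 0")


@dataclass(frozen=True)
class SliceScore:
    """Quantile summary of one slice ROI."""

    q_low: float
    q_high: float
    score: float
    n_pixels: int


@dataclass
class SliceImage:
    """One photographed root slice: grayscale pixels plus ROI mask."""

    pixels: np.ndarray
    roi: np.ndarray
    slice_position: str = "central"
    cultivar: str | None = None
    root_id: str | None = None
    dph: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.pixels.shape != self.roi.shape:
            raise ShapeError(
                f"pixels {self.pixels.shape} and roi {self.roi.shape} differ"
            )
        if self.slice_position not in SLICE_POSITIONS:
            raise ValueError(f"unknown slice position {self.slice_position!r}")
        if self.dph < 0:
            raise ValueError("dph must be non-negative")


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale intensities in [0, 1].

    Integer images are first divided by their code-value maximum (255 for
    8-bit, 65535 for 16-bit); float images must already lie in [0, 1].
    The conversion is the per-pixel luma sum 0.299 R + 0.587 G + 0.114 B.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ShapeError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(rgb.dtype).max
    else:
        arr = arr.astype(float)
    if np.isnan(arr).any():
        raise InvalidImageError("image contains NaN pixels")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidImageError("float RGB values must lie in [0, 1]")
    gray = arr @ np.asarray(LUMA_WEIGHTS)
    return np.clip(gray, 0.0, 1.0)


def detect_roi(gray: np.ndarray, params: RoiParams | None = None) -> np.ndarray:
    """Automatically locate the parenchyma disc of a slice photograph.

    The image is thresholded (Otsu by default), the side of the threshold
    that dominates the image border is taken as background, small components
    are discarded, the largest remaining component is kept, and the result
    is eroded by ``peel_erosion_px`` to exclude the peel ring.

    Raises
    ------
    DegenerateRoiError
        If no foreground component survives thresholding and erosion.
    """
    params = params or RoiParams()
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ShapeError(f"expected a 2-D grayscale array, got shape {gray.shape}")

    if params.background_threshold_mode == "fixed":
        thr = params.fixed_threshold
    else:
        if np.ptp(gray) == 0.0:
            raise DegenerateRoiError("constant image: no foreground to threshold")
        thr = threshold_otsu(gray)

    above = gray > thr
    border = np.concatenate([above[0], above[-1], above[:, 0], above[:, -1]])
    # The border is overwhelmingly background; the slice is the other side.
    foreground = above if border.mean() < 0.5 else ~above

    foreground = morphology.remove_small_objects(
        foreground, max_size=params.min_component_px - 1
    )
    if not foreground.any():
        raise DegenerateRoiError("no connected component above min_component_px")

    labels = measure.label(foreground, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    # Dark lesions inside the slice fall on the background side of the
    # threshold; fill those holes so the ROI keeps the symptomatic pixels.
    mask = ndimage.binary_fill_holes(mask)

    if params.peel_erosion_px > 0:
        mask = morphology.erosion(mask, morphology.disk(params.peel_erosion_px))
    if not mask.any():
        raise DegenerateRoiError(
            f"ROI empty after eroding by {params.peel_erosion_px} px"
        )
    return mask


def intensity_quantile(values: np.ndarray, q: float) -> float:
    """Empirical quantile of raw intensities.

    Linear interpolation between order statistics at rank ``q * (n - 1)``
    (the "type-7" convention); exact and deterministic.  The normalized
    histogram shown in reports is a display artifact only — quantiles are
    always computed from the raw pixel values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty vector")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile fraction {q} outside [0, 1]")
    return float(np.quantile(values, q, method="linear"))


def ppd_score_slice(slice_image: SliceImage) -> SliceScore:
    """PPD score of one slice: (Q97.5 - Q2.5) / Q97.5 over the ROI pixels.

    Raises
    ------
    DegenerateRoiError
        If the ROI has fewer than ``MIN_ROI_PIXELS`` pixels.
    DegenerateSliceError
        If the 97.5% quantile is essentially zero (all-black ROI), which
        signals an unusable photograph rather than an undamaged slice.
    """
    roi_values = slice_image.pixels[slice_image.roi]
    if roi_values.size < MIN_ROI_PIXELS:
        raise DegenerateRoiError(
            f"ROI has {roi_values.size} px, need >= {MIN_ROI_PIXELS}"
        )
    if np.isnan(roi_values).any():
        raise InvalidImageError("ROI contains NaN pixels")
    q_low = intensity_quantile(roi_values, Q_LOW)
    q_high = intensity_quantile(roi_values, Q_HIGH)
    if q_high <= EPS_Q_HIGH:
        raise DegenerateSliceError(
            f"upper quantile {q_high:.2e} <= {EPS_Q_HIGH}: all-black ROI"
        )
    score = (q_high - q_low) / q_high
    return SliceScore(
        q_low=q_low,
        q_high=q_high,
        score=float(np.clip(score, 0.0, 1.0)),
        n_pixels=int(roi_values.size),
    )


def roi_histogram(
    slice_image: SliceImage, bins: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized intensity histogram of the ROI pixels (report artifact).

    Returned frequencies integrate to 1 over [0, 1].  The histogram is for
    display only; the score's quantiles are always taken from the raw
    pixels, so any histogram-based quantile estimate can differ from the
    reported score by at most one bin width.
    """
    values = slice_image.pixels[slice_image.roi]
    if values.size == 0:
        raise DegenerateRoiError("empty ROI has no histogram")
    freq, edges = np.histogram(values, bins=bins, range=(0.0, 1.0), density=True)
    return freq, edges


@dataclass(frozen=True)
class RootScore:
    """Mean slice score of one root, with the number of contributing slices."""

    score: float
    n_slices: int
    positions: tuple[str, ...] = field(default=())


def ppd_score_root(
    slice_scores: Mapping[str, SliceScore | float] | Iterable[tuple[str, SliceScore | float]],
) -> RootScore:
    """Average the proximal/central/distal slice scores of one root.

    Accepts a mapping (or iterable of pairs) from slice position to a
    SliceScore or bare score.  One to three distinct positions are allowed;
    missing slices simply do not contribute.
    """
    items = list(slice_scores.items()) if isinstance(slice_scores, Mapping) else list(slice_scores)
    if not items:
        raise MissingRootError("no scoreable slice for this root")
    positions = [p for p, _ in items]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate slice positions: {positions}")
    unknown = set(positions) - set(SLICE_POSITIONS)
    if unknown:
        raise ValueError(f"unknown slice positions: {sorted(unknown)}")
    values = [s.score if isinstance(s, SliceScore) else float(s) for _, s in items]
    return RootScore(
        score=float(np.mean(values)),
        n_slices=len(values),
        positions=tuple(positions),
    )
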