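"""Myelin densitometry on 2D immunofluorescence sections.

Each section image is segmented within a region of interest into three
intensity classes -- background, autofluorescence, and specific signal --
by exact multi-Otsu thresholding (two thresholds maximizing between-class
variance on the 256-bin histogram).  The specific signal is the top class;
its mean intensity is the section's immunoreactivity and the per-subject
value is the unweighted mean over that subject's sections.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import polygon2mask
from skimage.filters import threshold_multiotsu, threshold_otsu

__all__ = [
    "DensitometryResult",
    "multi_otsu",
    "binarize_otsu_threshold",
    "roi_mask",
    "myelin_immunoreactivity",
    "subject_immunoreactivity",
]


@dataclass(frozen=True)
class DensitometryResult:
    """Three-class segmentation summary for one section ROI.

    ``immunoreactivity`` is the mean intensity of pixels strictly above
    the upper threshold ``t2`` (NaN when no pixel qualifies);
    ``specific_fraction`` is their area fraction of the ROI.
    """

    t1: float
    t2: float
    immunoreactivity: float
    specific_fraction: float
    n_roi_pixels: int

    def __post_init__(self) -> None:
        if not (0 <= self.t1 < self.t2 <= 255):
            raise ValueError(f"thresholds out of order: t1={self.t1}, t2={self.t2}")


def _roi_values(image: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D section image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    if roi is None:
        return image.ravel()
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError(
            f"ROI mask shape {roi.shape} does not match image shape {image.shape}"
        )
    if not roi.any():
        raise ValueError("ROI is empty")
    return image[roi]


def multi_otsu(
    image: np.ndarray, roi: np.ndarray | None = None, classes: int = 3
) -> tuple[float, ...]:
    """Multi-level Otsu thresholds over the 256-bin intensity histogram.

    Returns the ``classes - 1`` thresholds (for three classes: ``(t1, t2)``
    with ``t1 < t2``) that maximize between-class variance; the search is
    exact over threshold pairs.

    Raises
    ------
    ValueError
        If the ROI holds fewer distinct intensity values than classes.
    """
    values = _roi_values(image, roi)
    if np.unique(values).size < classes:
        raise ValueError(
            f"need at least {classes} distinct intensity values for "
            f"{classes}-class segmentation"
        )
    thresholds = threshold_multiotsu(values, classes=classes, nbins=256)
    return tuple(float(t) for t in thresholds)


def binarize_otsu_threshold(image: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Single Otsu threshold (two classes) over the 256-bin histogram."""
    values = _roi_values(image, roi)
    if np.unique(values).size < 2:
        raise ValueError("cannot threshold a constant image")
    return float(threshold_otsu(values, nbins=256))


def roi_mask(image_shape: tuple[int, int], polygon: Sequence[Sequence[float]]) -> np.ndarray:
    """Rasterize an ROI polygon of (x, y) vertices into a boolean mask.

    Vertices use pixel coordinates with x = column, y = row (the
    convention of the JSON ROI files).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be a sequence of at least 3 (x, y) vertices")
    if (
        poly[:, 0].min() < 0
        or poly[:, 1].min() < 0
        or poly[:, 0].max() > image_shape[1]
        or poly[:, 1].max() > image_shape[0]
    ):
        raise ValueError("ROI polygon extends outside the image bounds")
    # polygon2mask wants (row, col) vertex order
    return polygon2mask(image_shape, poly[:, ::-1])


def myelin_immunoreactivity(
    image: np.ndarray, roi: np.ndarray | Sequence[Sequence[float]] | None = None
) -> DensitometryResult:
    """Quantify specific myelin signal in one section ROI.

    ``roi`` may be a boolean mask, an (x, y) polygon, or None for the
    whole image.  The specific class is pixels strictly above the upper
    multi-Otsu threshold; when none exist the immunoreactivity is NaN and
    a warning is issued.
    """
    image = np.asarray(image)
    if roi is not None and not (isinstance(roi, np.ndarray) and roi.dtype == bool):
        roi = roi_mask(image.shape, roi)  # type: ignore[arg-type]
    t1, t2 = multi_otsu(image, roi, classes=3)
    values = _roi_values(image, roi)
    specific = values[values > t2]
    if specific.size == 0:
        warnings.warn("no pixel above the upper threshold; immunoreactivity missing")
        mean_ir = float("nan")
    else:
        mean_ir = float(specific.mean())
    return DensitometryResult(
        t1=t1,
        t2=t2,
        immunoreactivity=mean_ir,
        specific_fraction=specific.size / values.size,
        n_roi_pixels=int(values.size),
    )


def subject_immunoreactivity(sections: Iterable[DensitometryResult]) -> float:
    """Per-subject value: unweighted mean immunoreactivity over sections.

    Sections with missing immunoreactivity (no specific signal) are
    excluded; all-missing returns NaN.
    """
    vals = [s.immunoreactivity for s in sections if np.isfinite(s.immunoreactivity)]
    return float(np.mean(vals)) if vals else float("nan")
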