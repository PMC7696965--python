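"""Autofluorescence (VELscope) ROI quantification.

Two features per circular ROI, both dimensionless and invariant under global
linear rescaling of pixel intensities:

* normalized intensity     = ROI mean / whole-image mean,
* normalized heterogeneity = ROI pixel SD / whole-image mean.

Division by the whole-image mean neutralizes global brightness effects
(exposure, bright off-lesion structures such as teeth or prostheses inflate
the denominator for every ROI of that image alike).  Tumor ROIs are expected
to score low on normalized intensity (loss of autofluorescence) and high on
normalized heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidSpecError
from .synthetic import RoiImage, RoiRecord

__all__ = [
    "RoiFeatures",
    "roi_mask",
    "roi_raw_stats",
    "image_stats",
    "normalize_roi_features",
    "quantify_image",
    "quantify_cohort",
]

_CHANNEL_MODES = ("green", "luminance")


@dataclass(frozen=True)
class RoiFeatures:
    """Per-ROI feature record."""

    patient_id: str
    tissue_class: str
    norm_intensity: float
    norm_heterogeneity: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise InvalidSpecError("ROI must contain at least one pixel")
        if not (np.isfinite(self.norm_intensity) and np.isfinite(self.norm_heterogeneity)):
            raise InvalidSpecError("ROI features must be finite")
        if self.norm_heterogeneity < 0:
            raise InvalidSpecError("normalized heterogeneity must be >= 0")


def _channel(image: RoiImage, channel_mode: str) -> np.ndarray:
    if channel_mode == "green":
        return image.pixels[:, :, 1].astype(float)
    if channel_mode == "luminance":
        r, g, b = (image.pixels[:, :, i].astype(float) for i in range(3))
        return 0.299 * r + 0.587 * g + 0.114 * b
    raise InvalidSpecError(f"channel_mode must be one of {_CHANNEL_MODES}")


def roi_mask(image: RoiImage, roi: RoiRecord) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``roi.radius`` of the center.

    Pixel (row, col) belongs to the disc iff (row-cy)^2 + (col-cx)^2 <= r^2
    (inclusive boundary); coordinates are 0-based.
    """
    h, w, _ = image.pixels.shape
    if (
        roi.cx - roi.radius < 0
        or roi.cy - roi.radius < 0
        or roi.cx + roi.radius > w - 1
        or roi.cy + roi.radius > h - 1
    ):
        raise InvalidSpecError(
            f"ROI ({roi.cx}, {roi.cy}, r={roi.radius}) extends outside the {w}x{h} image"
        )
    yy, xx = np.ogrid[:h, :w]
    return (yy - roi.cy) ** 2 + (xx - roi.cx) ** 2 <= roi.radius**2


def roi_raw_stats(
    image: RoiImage, mask: np.ndarray, channel_mode: str = "green"
) -> tuple[float, float]:
    """Mean and population SD of the selected channel under ``mask``."""
    if not mask.any():
        raise InvalidSpecError("empty ROI mask")
    vals = _channel(image, channel_mode)[mask]
    return float(vals.mean()), float(vals.std(ddof=0))


def image_stats(
    image: RoiImage, channel_mode: str = "green", exclude_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Whole-image mean and population SD, optionally excluding masked pixels."""
    vals = _channel(image, channel_mode)
    if exclude_mask is not None:
        vals = vals[~exclude_mask]
        if vals.size == 0:
            raise DegenerateInputError("exclusion mask leaves no pixels")
    return float(vals.mean()), float(vals.std(ddof=0))


def normalize_roi_features(
    roi_stats: tuple[float, float],
    global_stats: tuple[float, float],
    *,
    patient_id: str,
    tissue_class: str,
    n_pixels: int,
) -> RoiFeatures:
    """Scale ROI statistics by the whole-image mean into dimensionless features."""
    global_mean = global_stats[0]
    if global_mean <= 0:
        raise DegenerateInputError("whole-image mean is not positive; cannot normalize")
    roi_mean, roi_sd = roi_stats
    return RoiFeatures(
        patient_id=patient_id,
        tissue_class=tissue_class,
        norm_intensity=roi_mean / global_mean,
        norm_heterogeneity=roi_sd / global_mean,
        n_pixels=n_pixels,
    )


def quantify_image(
    image: RoiImage,
    channel_mode: str = "green",
    exclude_roi_from_global: bool = False,
) -> list[RoiFeatures]:
    """Features for every ROI of one image.

    ``exclude_roi_from_global`` removes each ROI's own pixels from its
    normalization denominator; the default keeps them (simple, and exact scale
    invariance either way).
    """
    features = []
    for roi in image.rois:
        mask = roi_mask(image, roi)
        stats = roi_raw_stats(image, mask, channel_mode)
        gstats = image_stats(
            image, channel_mode, exclude_mask=mask if exclude_roi_from_global else None
        )
        features.append(
            normalize_roi_features(
                stats,
                gstats,
                patient_id=roi.patient_id,
                tissue_class=roi.tissue_class,
                n_pixels=int(mask.sum()),
            )
        )
    return features


def quantify_cohort(
    images: list[RoiImage],
    channel_mode: str = "green",
    exclude_roi_from_global: bool = False,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per ROI, two rows per patient.

    Indexed by sample_id ("patient:class"), ordered by (patient_id, class).
    """
    rows = []
    for image in images:
        for f in quantify_image(image, channel_mode, exclude_roi_from_global):
            rows.append(
                {
                    "sample_id": f"{f.patient_id}:{f.tissue_class}",
                    "patient_id": f.patient_id,
                    "tissue_class": f.tissue_class,
                    "norm_intensity": f.norm_intensity,
                    "norm_heterogeneity": f.norm_heterogeneity,
                    "n_pixels": f.n_pixels,
                }
            )
    df = pd.DataFrame(rows).sort_values(["patient_id", "tissue_class"]).set_index("sample_id")
    return df
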