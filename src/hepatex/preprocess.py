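"""Dynamic gray-level scaling and ROI-restricted Otsu vessel removal.

The pipeline quantizes the 12-bit acquisition range (0-4095) to 64 gray
levels (0-63), then removes hyperintense vessel pixels (arteries, portal
veins) from the liver ROI with an Otsu threshold computed on the ROI's
own intensity histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyRegionError
from .imaging_io import RawImage, ROIMask

logger = logging.getLogger(__name__)

N_LEVELS = 64  # quantized gray-level alphabet size
_DIVISOR = 4096 // N_LEVELS  # 64: floor(v / 64) maps 0->0, 4095->63


@dataclass
class ScaledImage:
    """2-D grid of gray levels in [0, 63] after dynamic scaling."""

    pixels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > N_LEVELS - 1
        ):
            raise ValueError("scaled values must lie in [0, 63]")


@dataclass
class OtsuResult:
    """Otsu split level; ``degenerate`` marks a single-valued input."""

    level: int
    degenerate: bool = False


@dataclass
class RetainedRegion:
    """ROI pixels surviving vessel filtering, with provenance counts."""

    mask: np.ndarray  # binary, subset of the ROI mask
    values: np.ndarray  # scaled intensities at retained pixels
    otsu_level: int
    n_roi: int
    n_retained: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_retained > self.n_roi:
            raise ValueError("retained count cannot exceed ROI count")


def scale_gray_levels(image: RawImage) -> ScaledImage:
    """Quantize a raw image from the (0, 4095) range to (0, 63).

    Uniform 64-level quantization: out = floor(in / 64), i.e. the 6
    least-significant bits are dropped.  Values above 4095 are clipped
    with a warning; the mapping is monotone non-decreasing.
    """
    pixels = image.pixels
    if pixels.size and pixels.max() > 4095:
        n_over = int((pixels > 4095).sum())
        logger.warning(
            "%s: %d pixel(s) above 4095 clipped before scaling",
            image.subject_id,
            n_over,
        )
        pixels = np.clip(pixels, 0, 4095)
    return ScaledImage(pixels // _DIVISOR, subject_id=image.subject_id)


def otsu_threshold(values: np.ndarray) -> OtsuResult:
    """Otsu split of gray levels in [0, 63] maximizing between-class variance.

    Returns the level k* maximizing w0(k) * w1(k) * (mu0(k) - mu1(k))^2 for
    the split {v <= k} vs {v > k} over k in [0, 62], ties broken by the
    smallest k.  A constant input is flagged degenerate and returns that
    constant.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise EmptyRegionError("cannot threshold an empty region")
    counts = np.bincount(values.astype(np.int64), minlength=N_LEVELS).astype(
        np.float64
    )
    if np.count_nonzero(counts) == 1:
        return OtsuResult(level=int(values[0]), degenerate=True)

    total = counts.sum()
    levels = np.arange(N_LEVELS, dtype=np.float64)
    w0 = np.cumsum(counts) / total  # P(v <= k)
    sum0 = np.cumsum(counts * levels)  # sum of values <= k
    grand = sum0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / np.cumsum(counts)
        mu1 = (grand - sum0) / (total - np.cumsum(counts))
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[: N_LEVELS - 1], nan=-np.inf)
    return OtsuResult(level=int(np.argmax(sigma_b)), degenerate=False)


def filter_vessels(
    image: ScaledImage, roi: ROIMask, side: str = "remove_above"
) -> RetainedRegion:
    """Remove vessel pixels from the ROI by Otsu thresholding.

    With ``side="remove_above"`` (the default; vessels are hyperintense on
    T2), pixels with scaled value <= Otsu level are retained.  A degenerate
    ROI (fewer than two distinct levels) retains all pixels with a warning:
    SD and entropy are then 0 downstream, the homogeneous-tissue limit.
    """
    if side not in ("remove_above", "remove_below"):
        raise ValueError(f"unknown side: {side!r}")
    if roi.mask.shape != image.pixels.shape:
        raise ValueError("ROI mask shape does not match image shape")
    inside = roi.mask.astype(bool)
    n_roi = int(inside.sum())
    if n_roi == 0:
        raise EmptyRegionError("ROI contains no pixels")
    roi_values = image.pixels[inside]

    if np.unique(roi_values).size < 2:
        logger.warning(
            "%s: ROI has a single gray level (%d); retaining all pixels",
            image.subject_id,
            int(roi_values[0]),
        )
        return RetainedRegion(
            mask=inside.astype(np.uint8),
            values=roi_values.copy(),
            otsu_level=int(roi_values[0]),
            n_roi=n_roi,
            n_retained=n_roi,
            degenerate=True,
        )

    otsu = otsu_threshold(roi_values)
    if side == "remove_above":
        keep = image.pixels <= otsu.level
    else:
        keep = image.pixels > otsu.level
    retained = inside & keep
    return RetainedRegion(
        mask=retained.astype(np.uint8),
        values=image.pixels[retained],
        otsu_level=otsu.level,
        n_roi=n_roi,
        n_retained=int(retained.sum()),
        degenerate=False,
    )
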