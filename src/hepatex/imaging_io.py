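"""Image, mask and table I/O for the cirrhosis-quantification pipeline.

Supported inputs are single-frame grayscale DICOM slices (the clinical
format) and 16-bit grayscale PNG/TIFF (the phantom format), each paired
with an 8-bit binary liver-ROI mask of identical dimensions.  Coordinates
are row-major with the origin at the top-left, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom

from .exceptions import MaskMismatchError, UnsupportedImageError

logger = logging.getLogger(__name__)

#: columns of the per-subject feature table, in write order
FEATURE_TABLE_COLUMNS = [
    "subject_id",
    "group",
    "mean",
    "sd",
    "entropy",
    "n_roi",
    "n_retained",
    "predicted_sd",
    "predicted_mean",
    "predicted_entropy",
    "status",
]


@dataclass
class RawImage:
    """A 2-D acquired intensity grid, typically a 12-bit T2-weighted slice."""

    pixels: np.ndarray
    subject_id: str = ""
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedImageError(
                f"expected a 2-D image, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise UnsupportedImageError("pixel values must be integers")
        if self.pixels.size and self.pixels.min() < 0:
            raise UnsupportedImageError("pixel values must be non-negative")
        if self.pixels.size and self.pixels.max() > 2**self.bit_depth - 1:
            raise UnsupportedImageError(
                f"pixel values exceed the {self.bit_depth}-bit range"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ROIMask:
    """Binary liver mask; 1 marks region-of-interest pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = (np.asarray(self.mask) != 0).astype(np.uint8)
        if self.mask.ndim != 2:
            raise UnsupportedImageError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class CohortRecord:
    subject_id: str
    group: str  # "normal" | "abnormal"
    image_path: str
    mask_path: str


@dataclass
class CohortTable:
    """Subject manifest: id, known group label and on-disk image/mask paths."""

    records: list[CohortRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                (r.subject_id, r.group, r.image_path, r.mask_path)
                for r in self.records
            ],
            columns=["subject_id", "group", "image_path", "mask_path"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, dtype=str)
        required = {"subject_id", "group", "image_path", "mask_path"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        return cls(
            [
                CohortRecord(r.subject_id, r.group, r.image_path, r.mask_path)
                for r in df.itertuples()
            ]
        )


def _infer_bit_depth(max_value: int) -> int:
    # 16-bit container, but treat data fitting the scanner's 12-bit range as 12-bit
    return 12 if max_value <= 4095 else 16


def read_image(path: str | Path, subject_id: str | None = None) -> RawImage:
    """Read a single-frame grayscale DICOM, PNG or TIFF image.

    For DICOM the stored pixel values are used; RescaleSlope/Intercept are
    applied only when both are present and yield integer values, since the
    pipeline operates on the scanner's stored (0, 4095) range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read image: {path}")
    sid = subject_id if subject_id is not None else path.stem

    if path.suffix.lower() in {".dcm", ".dicom"} or _looks_like_dicom(path):
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise UnsupportedImageError(
                f"{path}: multi-frame or color DICOM is not supported"
            )
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is not None and intercept is not None:
            rescaled = arr.astype(np.float64) * float(slope) + float(intercept)
            if np.allclose(rescaled, np.round(rescaled)):
                arr = np.round(rescaled).astype(np.int64)
            else:
                logger.warning(
                    "%s: non-integer rescale (slope=%s, intercept=%s); "
                    "using stored values",
                    path,
                    slope,
                    intercept,
                )
        bit_depth = int(getattr(ds, "BitsStored", 16))
        return RawImage(arr.astype(np.int64), subject_id=sid, bit_depth=bit_depth)

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as I/O error naming the path
        raise UnsupportedImageError(f"cannot read image: {path}: {exc}") from exc
    if arr.ndim != 2:
        raise UnsupportedImageError(f"{path}: color or multi-channel image")
    arr = arr.astype(np.int64)
    max_value = int(arr.max()) if arr.size else 0
    return RawImage(arr, subject_id=sid, bit_depth=_infer_bit_depth(max_value))


def _looks_like_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_mask(path: str | Path, image: RawImage) -> ROIMask:
    """Read a binary ROI mask (any nonzero byte = foreground) for ``image``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot read mask: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise UnsupportedImageError(f"{path}: mask must be single-channel")
    if arr.shape != image.pixels.shape:
        raise MaskMismatchError(
            f"{path}: mask shape {arr.shape} does not match image shape "
            f"{image.pixels.shape}"
        )
    return ROIMask(arr)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), ((np.asarray(mask) != 0) * 255).astype(np.uint8))


def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write integer pixel data as a 16-bit grayscale PNG."""
    arr = np.asarray(pixels)
    if arr.min() < 0 or arr.max() > 65535:
        raise UnsupportedImageError("pixel values outside the 16-bit range")
    iio.imwrite(Path(path), arr.astype(np.uint16))


def write_feature_table(records: Sequence, path: str | Path) -> None:
    """Write per-subject features to CSV (floats at 8 significant digits).

    ``records`` are SubjectFeatures objects (see texture_features) or
    equivalent mappings with the same field names.
    """
    if len(records) == 0:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        if hasattr(rec, "as_row"):
            rows.append(rec.as_row())
        else:
            rows.append(dict(rec))
    df = pd.DataFrame(rows)
    for col in FEATURE_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col.startswith(("predicted", "status", "group")) else np.nan
    df = df[FEATURE_TABLE_COLUMNS]
    df.to_csv(path, index=False, float_format="%.8g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV, validating the evaluation-relevant schema."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "mean", "sd", "entropy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df
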