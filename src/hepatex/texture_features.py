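"""First-order texture features of the vessel-filtered liver ROI.

Three features are computed on the retained scaled intensities: the mean,
the sample standard deviation, and the Shannon entropy (bits) of the
64-bin gray-level histogram.  Cirrhotic parenchyma is darker and more
homogeneous on these T2 slices, so smaller values of all three features
indicate abnormality; classification compares each feature against an
inclusive quantitative-value (QV) cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyRegionError
from .preprocess import N_LEVELS, RetainedRegion

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("sd", "mean", "entropy")

NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass(frozen=True)
class QVThresholds:
    """Per-feature abnormality cut-offs (feature <= QV => abnormal).

    Defaults are the published operating points for SD, mean and entropy.
    """

    sd_qv: float = 2.8
    mean_qv: float = 0.7
    entropy_qv: float = 0.3

    def __post_init__(self) -> None:
        if min(self.sd_qv, self.mean_qv, self.entropy_qv) <= 0:
            raise ValueError("QV cut-offs must be strictly positive")

    def for_feature(self, name: str) -> float:
        return {"sd": self.sd_qv, "mean": self.mean_qv, "entropy": self.entropy_qv}[
            name
        ]


@dataclass
class FeatureVector:
    mean: float
    sd: float
    entropy: float
    n_roi: int
    n_retained: int

    def value(self, name: str) -> float:
        return {"sd": self.sd, "mean": self.mean, "entropy": self.entropy}[name]


@dataclass
class SubjectFeatures:
    """One subject's features plus per-feature predicted labels."""

    subject_id: str
    group: str  # known label, or "unknown"
    features: FeatureVector | None
    predicted: dict[str, str] = field(default_factory=dict)
    status: str = "ok"

    def as_row(self) -> dict:
        fv = self.features
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "mean": fv.mean if fv else np.nan,
            "sd": fv.sd if fv else np.nan,
            "entropy": fv.entropy if fv else np.nan,
            "n_roi": fv.n_roi if fv else 0,
            "n_retained": fv.n_retained if fv else 0,
            "predicted_sd": self.predicted.get("sd", ""),
            "predicted_mean": self.predicted.get("mean", ""),
            "predicted_entropy": self.predicted.get("entropy", ""),
            "status": self.status,
        }


def compute_features(region: RetainedRegion) -> FeatureVector:
    """Mean, sample SD and histogram entropy of the retained gray levels.

    SD uses the n-1 denominator (0 for a single pixel, with a warning).
    Entropy is -sum p_i log2 p_i over the 64-bin histogram with
    p_i = count_i / n and 0 log 0 = 0, so 0 <= entropy <= 6 bits.
    """
    values = np.asarray(region.values, dtype=np.float64)
    if values.size == 0:
        raise EmptyRegionError("cannot compute features of an empty region")
    mean = float(values.mean())
    if values.size < 2:
        logger.warning("single-pixel region: SD reported as 0")
        sd = 0.0
    else:
        sd = float(values.std(ddof=1))
    counts = np.bincount(values.astype(np.int64), minlength=N_LEVELS)
    p = counts[counts > 0] / values.size
    entropy = float(-(p * np.log2(p)).sum())
    return FeatureVector(
        mean=mean,
        sd=sd,
        entropy=entropy,
        n_roi=region.n_roi,
        n_retained=region.n_retained,
    )


def classify(features: FeatureVector, qv: QVThresholds | None = None) -> dict[str, str]:
    """Label each feature abnormal iff its value is <= the QV cut-off."""
    qv = qv or QVThresholds()
    if not all(np.isfinite([features.mean, features.sd, features.entropy])):
        raise ValueError("features must be finite")
    return {
        name: (ABNORMAL if features.value(name) <= qv.for_feature(name) else NORMAL)
        for name in FEATURE_NAMES
    }
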