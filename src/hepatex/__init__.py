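"""hepatex: quantification of liver cirrhosis from T2-weighted MR slices.

The pipeline scales the 12-bit intensity range to 64 gray levels, removes
bright vessels from a user-supplied liver ROI by Otsu thresholding, and
computes first-order texture features (mean, SD, entropy) whose small
values indicate cirrhotic parenchyma.  A diagnostic-statistics layer
(ROC/AUC, operating points, kappa, t-tests, confidence intervals)
evaluates the features as classifiers, and a phantom generator provides
synthetic cohorts with the same group structure.
"""

from __future__ import annotations

from . import diagstats, imaging_io, phantom, preprocess, texture_features
from .diagstats import evaluate_cohort
from .imaging_io import RawImage, ROIMask, read_image, read_mask
from .preprocess import filter_vessels, scale_gray_levels
from .texture_features import (
    QVThresholds,
    SubjectFeatures,
    classify,
    compute_features,
)

__version__ = "0.1.0"

__all__ = [
    "RawImage",
    "ROIMask",
    "QVThresholds",
    "SubjectFeatures",
    "read_image",
    "read_mask",
    "scale_gray_levels",
    "filter_vessels",
    "compute_features",
    "classify",
    "evaluate_cohort",
    "quantify_subject",
    "diagstats",
    "imaging_io",
    "phantom",
    "preprocess",
    "texture_features",
]


def quantify_subject(
    image: RawImage,
    roi: ROIMask,
    group: str = "unknown",
    qv: QVThresholds | None = None,
    vessel_side: str = "remove_above",
) -> SubjectFeatures:
    """Run the full single-subject pipeline: scale, filter vessels, extract.

    Returns the subject's FeatureVector together with per-feature
    normal/abnormal predictions against the QV cut-offs.
    """
    scaled = scale_gray_levels(image)
    region = filter_vessels(scaled, roi, side=vessel_side)
    features = compute_features(region)
    return SubjectFeatures(
        subject_id=image.subject_id,
        group=group,
        features=features,
        predicted=classify(features, qv),
    )
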