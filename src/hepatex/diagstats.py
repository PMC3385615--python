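"""Diagnostic-evaluation statistics: ROC/AUC, operating points, agreement.

Everything needed to evaluate the three texture features as binary
classifiers of cirrhosis: group summaries with 95% confidence intervals,
two-sample t-tests, ROC curves with the lower-value-is-positive
direction, trapezoidal AUC (equal to the Mann-Whitney estimator),
Youden-optimal operating points, confusion-matrix rates, Cohen's kappa,
and AUC significance under the Hanley-McNeil normal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import EmptyRegionError, EvaluationError, UndefinedStatisticError
from .texture_features import ABNORMAL, FEATURE_NAMES, NORMAL, QVThresholds

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrices and agreement


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with "abnormal" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(
        cls, true: Sequence[str], predicted: Sequence[str]
    ) -> "ConfusionMatrix":
        if len(true) != len(predicted):
            raise ValueError("label sequences differ in length")
        t = np.asarray(true) == ABNORMAL
        p = np.asarray(predicted) == ABNORMAL
        return cls(
            tp=int((t & p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
            tn=int((~t & ~p).sum()),
        )


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV.

    A rate whose denominator is zero is reported as None (undefined),
    never as a silent NaN.
    """
    if cm.total == 0:
        raise EmptyRegionError("empty confusion matrix")

    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": _rate(cm.tp, cm.tp + cm.fn),
        "specificity": _rate(cm.tn, cm.tn + cm.fp),
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "ppv": _rate(cm.tp, cm.tp + cm.fp),
        "npv": _rate(cm.tn, cm.tn + cm.fn),
    }


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_e is the expected agreement of the marginal distributions.  When the
    two true groups are of equal size, p_e = 1/2 and kappa reduces to
    2 * accuracy - 1.  Returns 1 for perfect agreement even when p_e = 1.
    """
    n = cm.total
    if n == 0:
        raise EmptyRegionError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (
        n * n
    )
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def confusion_from_rates(
    ppv: float,
    npv: float,
    accuracy: float,
    n_pos: int,
    n_neg: int,
    decimals: int = 3,
) -> ConfusionMatrix:
    """Reconstruct the integer 2x2 table behind printed (PPV, NPV, accuracy).

    Enumerates all (tp, tn) with the given true-group sizes and returns the
    matrix whose rates round to the printed values.  Raises if no matrix or
    more than one matrix matches.
    """
    matches = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for tn in range(n_neg + 1):
            fp = n_neg - tn
            cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
            m = confusion_metrics(cm)
            if m["ppv"] is None or m["npv"] is None:
                continue
            if (
                round(m["ppv"], decimals) == round(ppv, decimals)
                and round(m["npv"], decimals) == round(npv, decimals)
                and round(m["accuracy"], decimals) == round(accuracy, decimals)
            ):
                matches.append(cm)
    if not matches:
        raise ValueError("no confusion matrix is consistent with the printed rates")
    if len(matches) > 1:
        raise ValueError(f"printed rates are ambiguous: {matches}")
    return matches[0]


# ---------------------------------------------------------------------------
# ROC analysis (lower score => positive/abnormal)


@dataclass
class ROCCurve:
    """ROC with the lower-value-is-positive convention.

    ``thresholds[i]`` classifies a subject abnormal iff score <= threshold;
    a leading -inf sentinel provides the (0, 0) corner.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.spec


def roc_curve(
    scores_normal: Sequence[float], scores_abnormal: Sequence[float]
) -> ROCCurve:
    """ROC over all observed thresholds; abnormal subjects score lower.

    The trapezoidal AUC equals the Mann-Whitney estimator
    P(abnormal < normal) + P(tie) / 2.
    """
    neg = np.asarray(scores_normal, dtype=np.float64)
    pos = np.asarray(scores_abnormal, dtype=np.float64)
    if neg.size == 0 or pos.size == 0:
        raise EvaluationError("both groups must be non-empty for a ROC curve")
    thresholds = np.concatenate(([-np.inf], np.unique(np.concatenate([neg, pos]))))
    sens = np.array([(pos <= t).mean() for t in thresholds])
    spec = np.array([(neg > t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def convex_point(roc: ROCCurve, rule: str = "youden") -> float:
    """Operating threshold at the ROC's optimal ("convex") point.

    ``youden`` maximizes J = sensitivity + specificity - 1;
    ``closest-topleft`` minimizes the distance to (FPR, TPR) = (0, 1).
    Ties are broken by the smallest threshold among observed scores (the
    -inf sentinel is never returned).
    """
    finite = slice(1, None)  # drop the -inf sentinel
    thr = roc.thresholds[finite]
    sens = roc.sens[finite]
    spec = roc.spec[finite]
    if rule == "youden":
        # integer objective n_neg*TP + n_pos*TN so exact ties break exactly
        tp = np.rint(sens * roc.n_pos).astype(np.int64)
        tn = np.rint(spec * roc.n_neg).astype(np.int64)
        objective = roc.n_neg * tp + roc.n_pos * tn
        idx = int(np.argmax(objective))
    elif rule == "closest-topleft":
        objective = -((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
        idx = int(np.argmax(objective))
    else:
        raise ValueError(f"unknown operating-point rule: {rule!r}")
    return float(thr[idx])


def auc_significance(
    roc: ROCCurve | float, n_pos: int | None = None, n_neg: int | None = None
) -> float:
    """Two-sided p-value for AUC != 0.5 (Hanley-McNeil normal approximation).

    The standard error is evaluated under the null A = 0.5, where
    Q1 = Q2 = 1/3, giving SE^2 = (1/4 + (n_pos + n_neg - 2) / 12) /
    (n_pos * n_neg); z = (AUC - 1/2) / SE.
    """
    if isinstance(roc, ROCCurve):
        auc = roc.auc
        n_pos = roc.n_pos if n_pos is None else n_pos
        n_neg = roc.n_neg if n_neg is None else n_neg
    else:
        auc = float(roc)
    if n_pos is None or n_neg is None or n_pos < 2 or n_neg < 2:
        raise ValueError("need n_pos, n_neg >= 2")
    if auc in (0.0, 1.0) and min(n_pos, n_neg) < 10:
        logger.warning("degenerate AUC=%g with small n; p-value is approximate", auc)
    se = math.sqrt((0.25 + (n_pos + n_neg - 2) / 12.0) / (n_pos * n_neg))
    z = (auc - 0.5) / se
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# group summaries, t-tests, confidence intervals


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    @classmethod
    def from_samples(cls, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=np.float64)
        if v.size < 2:
            raise ValueError("need at least two observations per group")
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        low, high = ci95(mean, sd, v.size)
        return cls(n=v.size, mean=mean, sd=sd, ci_low=low, ci_high=high)


def ci95(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Two-sided 95% t-interval: mean +/- t_{0.975, n-1} * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return (mean - half, mean + half)


def _as_summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_samples(x)


def two_sample_t(
    a: GroupSummary | Sequence[float],
    b: GroupSummary | Sequence[float],
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from raw samples or summary statistics.

    Returns (t, df, p).  ``pooled`` uses the equal-variance statistic with
    df = n_a + n_b - 2; ``welch`` uses the Satterthwaite df.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("need n >= 2 in both groups")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    va, vb = sa.sd**2, sb.sd**2
    if va == 0 and vb == 0:
        if sa.mean == sb.mean:
            raise UndefinedStatisticError(
                "t undefined: zero variance in both groups with equal means"
            )
        return (math.inf if sa.mean > sb.mean else -math.inf, sa.n + sb.n - 2, 0.0)
    if variant == "pooled":
        df = sa.n + sb.n - 2
        sp2 = ((sa.n - 1) * va + (sb.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / sa.n + 1 / sb.n))
    else:
        sea2, seb2 = va / sa.n, vb / sb.n
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (
            sea2**2 / (sa.n - 1) + seb2**2 / (sb.n - 1)
        )
    t = (sa.mean - sb.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return (t, df, p)


# ---------------------------------------------------------------------------
# cohort-level evaluation


@dataclass
class FeatureEvaluation:
    """Evaluation of one feature as a classifier (one report column)."""

    feature: str
    qv: float
    qv_source: str  # "supplied" | "auto"
    summary_normal: GroupSummary
    summary_abnormal: GroupSummary
    t_statistic: float
    t_df: float
    t_p_value: float
    auc: float
    auc_p_value: float
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    kappa: float

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "qv": self.qv,
            "qv_source": self.qv_source,
            "normal": {
                "n": self.summary_normal.n,
                "mean": self.summary_normal.mean,
                "sd": self.summary_normal.sd,
                "ci95": [self.summary_normal.ci_low, self.summary_normal.ci_high],
            },
            "abnormal": {
                "n": self.summary_abnormal.n,
                "mean": self.summary_abnormal.mean,
                "sd": self.summary_abnormal.sd,
                "ci95": [self.summary_abnormal.ci_low, self.summary_abnormal.ci_high],
            },
            "t_test": {
                "t": self.t_statistic,
                "df": self.t_df,
                "p_value": self.t_p_value,
            },
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            **{k: v for k, v in self.metrics.items()},
            "kappa": self.kappa,
            "auc": self.auc,
            "auc_p_value": self.auc_p_value,
        }


@dataclass
class EvaluationReport:
    per_feature: dict[str, FeatureEvaluation]
    n_normal: int
    n_abnormal: int

    def to_dict(self) -> dict:
        return {
            "n_normal": self.n_normal,
            "n_abnormal": self.n_abnormal,
            "features": {k: v.to_dict() for k, v in self.per_feature.items()},
        }


def evaluate_cohort(
    subjects: Iterable,
    qv: QVThresholds | str | None = None,
    operating_point: str = "youden",
    ttest: str = "pooled",
) -> EvaluationReport:
    """Assemble the full per-feature diagnostic report for a labelled cohort.

    ``subjects`` are SubjectFeatures objects or mappings with group, mean,
    sd and entropy fields.  ``qv="auto"`` derives each cut-off from the
    ROC's optimal operating point; otherwise the supplied (or default
    published) QVs are used.  Deterministic given its inputs.
    """
    rows = []
    for s in subjects:
        if hasattr(s, "features"):
            if s.features is None:
                continue
            rows.append(
                {
                    "group": s.group,
                    "sd": s.features.sd,
                    "mean": s.features.mean,
                    "entropy": s.features.entropy,
                }
            )
        else:
            rows.append({k: s[k] for k in ("group", "sd", "mean", "entropy")})
    groups = {r["group"] for r in rows}
    if not {NORMAL, ABNORMAL} <= groups:
        raise EvaluationError(
            f"evaluation needs both groups; found {sorted(groups) or 'none'}"
        )

    auto = isinstance(qv, str) and qv == "auto"
    fixed = qv if isinstance(qv, QVThresholds) else QVThresholds()

    per_feature: dict[str, FeatureEvaluation] = {}
    for name in FEATURE_NAMES:
        normal = [r[name] for r in rows if r["group"] == NORMAL]
        abnormal = [r[name] for r in rows if r["group"] == ABNORMAL]
        roc = roc_curve(normal, abnormal)
        cut = convex_point(roc, rule=operating_point) if auto else fixed.for_feature(name)
        true = [NORMAL] * len(normal) + [ABNORMAL] * len(abnormal)
        pred = [
            ABNORMAL if v <= cut else NORMAL for v in list(normal) + list(abnormal)
        ]
        cm = ConfusionMatrix.from_labels(true, pred)
        t, df, p = two_sample_t(normal, abnormal, variant=ttest)
        per_feature[name] = FeatureEvaluation(
            feature=name,
            qv=cut,
            qv_source="auto" if auto else "supplied",
            summary_normal=GroupSummary.from_samples(normal),
            summary_abnormal=GroupSummary.from_samples(abnormal),
            t_statistic=t,
            t_df=df,
            t_p_value=p,
            auc=roc.auc,
            auc_p_value=auc_significance(roc),
            confusion=cm,
            metrics=confusion_metrics(cm),
            kappa=cohen_kappa(cm),
        )
    return EvaluationReport(
        per_feature=per_feature,
        n_normal=len([r for r in rows if r["group"] == NORMAL]),
        n_abnormal=len([r for r in rows if r["group"] == ABNORMAL]),
    )
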