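"""Seeded synthetic T2-like liver phantoms.

Each phantom is a 12-bit slice with an elliptical "liver" filled with
spatially correlated Gaussian texture on a noisy dark background, plus
bright circular "vessels" inside the ROI.  The two groups reproduce the
qualitative structure of cirrhotic vs normal parenchyma on T2: the
abnormal group is darker (lower base level) and more homogeneous (smaller
texture sd), so its mean, SD and entropy features are all smaller.
Output is a pure function of (params, group, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import PhantomParameterError
from .imaging_io import (
    CohortRecord,
    CohortTable,
    RawImage,
    ROIMask,
    write_image_png,
    write_mask,
)

logger = logging.getLogger(__name__)

MAX_INTENSITY = 4095  # 12-bit ceiling


@dataclass(frozen=True)
class GroupAppearance:
    """Parenchyma intensity model for one group (raw 12-bit units).

    ``heterogeneity_sd`` is the within-ROI texture sd after smoothing;
    ``between_subject_sd`` jitters each subject's base level.
    """

    base_level: float
    heterogeneity_sd: float
    between_subject_sd: float


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of the synthetic cohort."""

    shape: tuple[int, int] = (128, 128)
    liver_center: tuple[float, float] = (64.0, 64.0)
    liver_semiaxes: tuple[float, float] = (44.0, 30.0)
    background_level: float = 80.0
    background_noise_sd: float = 10.0
    normal: GroupAppearance = field(
        default_factory=lambda: GroupAppearance(900.0, 160.0, 60.0)
    )
    abnormal: GroupAppearance = field(
        default_factory=lambda: GroupAppearance(300.0, 40.0, 30.0)
    )
    correlation_length: float = 2.0
    n_vessels: int = 6
    vessel_radius: tuple[float, float] = (2.0, 4.0)
    vessel_level: float = 3500.0
    seed: int = 0

    def __post_init__(self) -> None:
        cy, cx = self.liver_center
        ay, ax = self.liver_semiaxes
        h, w = self.shape
        if ay <= 0 or ax <= 0 or cy - ay < 0 or cy + ay > h or cx - ax < 0 or cx + ax > w:
            raise PhantomParameterError("liver ellipse does not fit in the image")
        for g in (self.normal, self.abnormal):
            if not (0 <= g.base_level <= MAX_INTENSITY):
                raise PhantomParameterError("base level outside the 12-bit range")
            if self.vessel_level <= g.base_level + 3 * g.heterogeneity_sd:
                raise PhantomParameterError(
                    "vessel level must exceed parenchyma level + 3*heterogeneity sd"
                )
        if not (0 <= self.vessel_level <= MAX_INTENSITY):
            raise PhantomParameterError("vessel level outside the 12-bit range")
        if self.vessel_radius[0] > self.vessel_radius[1] or self.vessel_radius[0] <= 0:
            raise PhantomParameterError("invalid vessel radius range")

    def appearance(self, group: str) -> GroupAppearance:
        if group not in ("normal", "abnormal"):
            raise ValueError(f"unknown group: {group!r}")
        return self.normal if group == "normal" else self.abnormal


@dataclass
class PhantomSubject:
    image: RawImage
    roi: ROIMask
    vessel_mask: np.ndarray  # ground-truth vessel pixels, subset of the ROI
    group: str
    seed: int


def _ellipse_mask(params: PhantomParams) -> np.ndarray:
    h, w = params.shape
    cy, cx = params.liver_center
    ay, ax = params.liver_semiaxes
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_phantom(
    params: PhantomParams, group: str, seed: int | None = None
) -> PhantomSubject:
    """Generate one phantom subject; deterministic given (params, group, seed)."""
    appearance = params.appearance(group)
    used_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    h, w = params.shape

    img = params.background_level + rng.normal(0.0, params.background_noise_sd, (h, w))
    liver = _ellipse_mask(params)

    # correlated texture: smoothed white noise renormalized to unit sd in the
    # ROI so heterogeneity_sd is the realized within-ROI sd
    white = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(white, params.correlation_length)
    roi_sd = smooth[liver].std()
    if roi_sd > 0:
        smooth = smooth / roi_sd
    base = appearance.base_level + rng.normal(0.0, appearance.between_subject_sd)
    img[liver] = base + appearance.heterogeneity_sd * smooth[liver]

    # bright circular vessels fully inside the ellipse
    vessel_mask = np.zeros((h, w), dtype=bool)
    cy, cx = params.liver_center
    ay, ax = params.liver_semiaxes
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(params.n_vessels):
        r = rng.uniform(*params.vessel_radius)
        # rejection-sample a center whose disc stays inside the ellipse
        for _attempt in range(1000):
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1:
                continue
            y0 = cy + u * (ay - r)
            x0 = cx + v * (ax - r)
            if ((y0 - cy) / (ay - r)) ** 2 + ((x0 - cx) / (ax - r)) ** 2 <= 1.0:
                break
        disc = (yy - y0) ** 2 + (xx - x0) ** 2 <= r * r
        vessel_mask |= disc & liver
    img[vessel_mask] = params.vessel_level

    pixels = np.clip(np.round(img), 0, MAX_INTENSITY).astype(np.int64)
    return PhantomSubject(
        image=RawImage(pixels, subject_id=f"{group}-{used_seed}", bit_depth=12),
        roi=ROIMask(liver.astype(np.uint8)),
        vessel_mask=vessel_mask,
        group=group,
        seed=used_seed,
    )


def generate_cohort(
    params: PhantomParams,
    n_normal: int = 31,
    n_abnormal: int = 31,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[CohortTable, list[PhantomSubject]]:
    """Generate a labelled phantom cohort (defaults: 31 + 31 subjects).

    Per-subject seeds are master_seed + index, so subjects are independent
    and the cohort is reproducible.  When ``output_dir`` is given, images
    are written as 16-bit PNGs and masks as 8-bit PNGs, and the returned
    CohortTable points at the files; otherwise paths are empty strings.
    """
    if n_normal < 1 or n_abnormal < 1:
        raise ValueError("need at least one subject per group")
    master = params.seed if seed is None else seed
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    records: list[CohortRecord] = []
    subjects: list[PhantomSubject] = []
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    for idx, group in enumerate(labels):
        subject_seed = master + idx
        subj = generate_phantom(params, group, seed=subject_seed)
        sid = f"{group}_{idx:03d}"
        subj.image.subject_id = sid
        image_path = mask_path = ""
        if out is not None:
            image_path = str(out / f"{sid}.png")
            mask_path = str(out / f"{sid}_mask.png")
            write_image_png(subj.image.pixels, image_path)
            write_mask(subj.roi.mask, mask_path)
        records.append(CohortRecord(sid, group, image_path, mask_path))
        subjects.append(subj)
        logger.debug("generated %s (seed=%d)", sid, subject_seed)

    table = CohortTable(records)
    if out is not None:
        table.to_csv(out / "cohort.csv")
    return table, subjects
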