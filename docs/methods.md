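# Methods

## Pipeline

One 2-D T2-weighted slice per subject (12-bit intensities, DICOM or
16-bit grayscale PNG/TIFF) and a binary liver-ROI mask of identical
dimensions are the inputs. Processing is:

1. **Gray-level quantization.** `s = ⌊v/64⌋` maps the (0, 4095) range
   onto 64 levels (0–63). The floor form was chosen over
   `round(v·63/4095)` because it is an exact uniform 64-level
   quantization hitting both stated endpoints (0→0, 4095→63), it is
   monotone, and it is trivially invertible on multiples of 64. Values
   above 4095 are clipped with a logged warning rather than rejected.
2. **Vessel removal.** Otsu's threshold is computed on the ROI's own
   scaled histogram: the level `k* ∈ [0, 62]` maximizing
   `σ²_b(k) = w₀(k)·w₁(k)·(μ₀(k) − μ₁(k))²` for the split
   `{v ≤ k}` vs `{v > k}`, ties broken by the smallest `k` for
   determinism. By default pixels **above** the threshold are removed,
   because vessels and bile are hyperintense relative to parenchyma on
   this sequence; the polarity is exposed (`--vessel-side`) since either
   convention is defensible. Thresholding runs on the scaled 0–63
   values, matching the order of the pipeline steps. A ROI with a single
   gray level cannot be split; it is retained whole with a warning — SD
   and entropy are then 0, the homogeneous-tissue limit, which is
   exactly the reading the classifier gives to severe cirrhosis.
3. **Features.** On the retained pixels: arithmetic mean, sample SD
   (n−1 denominator, matching how group-level SDs are conventionally
   reported), and Shannon entropy in bits over the full 64-bin alphabet
   (`0·log 0 ≡ 0`), so `0 ≤ H ≤ 6`. No further normalization is applied.
4. **Classification.** `feature ≤ QV ⇒ abnormal`, with the boundary
   assigned to abnormal (inclusive cut-off). Default QVs 2.8 / 0.7 / 0.3
   for SD / mean / entropy are the published operating points.

Note the published clinical feature magnitudes (group means < 1 for the
mean feature on a 0–63 scale, entropies < 0.5 bits) are not derivable
from this pipeline as stated — they suggest an additional undocumented
normalization in the original analysis. Magnitudes are therefore not a
validation surface here; orderings (abnormal < normal in all three
features) and the evaluation layer are.

## Evaluation layer

* **Group summaries**: mean, sample SD and the 95% t-interval
  `mean ± t₀.₉₇₅,ₙ₋₁·sd/√n`. These reproduce all published interval
  bounds from the published (mean, SD, n) to within one unit in the last
  printed digit.
* **t-tests**: pooled-variance by default (`df = n₁+n₂−2`) — the
  published p-values are consistent with pooled df = 60, not with Welch —
  with Welch available as a variant. Accepts raw samples or summary
  statistics.
* **ROC**: direction fixed as lower-score ⇒ positive (abnormal), since
  all three features decrease with disease. Thresholds are the observed
  scores plus a −∞ sentinel; AUC is the trapezoidal area, which equals
  the Mann–Whitney estimator `P(abnormal < normal) + ½P(tie)` (verified
  against exhaustive pair counting).
* **Operating point**: the "convex point" of the ROC is implemented as
  the Youden-J maximum, the standard reading of an optimal ROC corner;
  a closest-to-top-left rule is offered as an alternative. The Youden
  argmax uses the integer objective `n₋·TP + n₊·TN` so exact ties are
  broken by the smallest threshold without floating-point noise.
* **Agreement**: Cohen's kappa from the 2×2 table. With equal true group
  sizes the chance agreement is exactly ½, so κ = 2·accuracy − 1; this
  identity reproduces the published kappas (0.677, 0.774, 0.806) from
  the published rates.
* **AUC significance**: Hanley–McNeil normal approximation with the
  standard error evaluated under the null A = ½ (where Q₁ = Q₂ = 1/3):
  `SE² = (¼ + (n₊+n₋−2)/12)/(n₊n₋)`, `z = (AUC − ½)/SE`, two-sided.
  This choice reproduces all three published AUC p-values from the
  published AUCs within print-precision slack, which strongly suggests
  it is the method originally used.
* p-values are reported at full double precision; no multiple-testing
  correction is applied across the three features.

A note on the published performance table: its sensitivity/specificity
rows are inconsistent with 31 subjects per group (0.963·31 is not an
integer) but match PPV/NPV exactly for integer 2×2 tables that also match
the printed accuracies. The reconstruction used by `confusion_from_rates`
therefore matches on (PPV, NPV, accuracy), which identifies a unique
table per feature; accuracy and kappa are the trusted cells.

## Phantom generator

Each phantom is a 128×128 12-bit slice: a dark noisy background
(level 80 ± 10), an elliptical liver (semi-axes 44×30 at the centre)
filled with correlated Gaussian texture, and 6 bright circular vessels
(radius 2–4 px, level 3500) fully inside the ellipse. Texture is white
noise smoothed by a Gaussian kernel (correlation length 2 px) and
renormalized to unit variance inside the ROI, so the heterogeneity
parameter is the *realized* within-ROI SD in raw units — smoothing does
not silently attenuate it. Group parameters: normal parenchyma base 900,
heterogeneity 160; abnormal base 300, heterogeneity 40 (darker and more
homogeneous, the cirrhotic contrast). Per-subject base levels are
jittered (SD 60 / 30 raw units) as between-patient variation. Cohorts
default to 31 + 31 subjects; per-subject seeds are master seed + index,
so output is a pure function of (parameters, group, seed), and cohorts
are bit-reproducible.

What the phantom does **not** emulate: anatomical liver shape, MR
physics (bias fields, k-space artefacts, partial volume), scanner-to-
scanner intensity variation, and the overlap structure of the clinical
feature distributions — at the default effect size the groups separate
completely (AUC = 1), whereas the clinical AUCs were 0.93–0.97. Passing
phantom tests therefore demonstrates correct mechanics (scaling,
thresholding, feature math, evaluation statistics) and recovery of a
known contrast, not clinical performance. A null configuration with
identical group parameters is used to check the other direction: AUC
falls to chance.

With no vessels and *textured* parenchyma, Otsu still splits the texture
and removes its bright tail — full retention (`n_retained = n_roi`) is
only guaranteed in the homogeneous limit, and the tests state it there.

## Degenerate inputs and numerical choices

* Empty ROI → error; single-level ROI → retain all, warn.
* Single retained pixel → SD reported as 0 with a warning.
* Undefined rates (zero denominator) are reported as `None`/`undef`,
  never silent NaN.
* Zero variance in both t-test groups with equal means → explicit error;
  with unequal means, t = ±∞, p = 0.
* Per-subject extraction failures mark the row and continue; evaluation
  drops marked rows.

## Problem sizes

Test-suite simulations use the study-sized 31+31 cohort at 128×128
pixels (fractions of a second per cohort), 100 phantom pairs for the
ordering Monte Carlo, 200 random instances per oracle-equivalence suite,
and 1000 replicates for t-test type-I calibration. The acceptance script
runs one 31+31 cohort.

## Interface conventions

Images are row-major, origin top-left, 0-based. Any nonzero mask byte is
foreground. DICOM rescale slope/intercept are applied only when both are
present and produce integers (the pipeline operates on stored 12-bit
values). Phantoms are written as 16-bit PNG rather than DICOM. The CLI
(`simulate`, `extract`, `evaluate`) follows click's exit-code
convention: 0 success (possibly with warnings), 2 usage error, 1 data
error. A YAML config may supply any option; explicit flags override it.
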