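# Methods

## Problem and scope

Visual scoring of cutaneous chronic graft-versus-host disease (cGVHD)
relies on estimating the fraction of skin surface affected, a quantity
with poor inter-observer reliability. One practical route to scalable
demarcation is a crowd of untrained raters outlining affected skin on
photographs, fused into a per-image consensus mask. `skincrowd`
implements that whole study design as a simulable, testable pipeline:

1. a synthetic-data generator producing multi-view skin images with
   expert-style ground truth and crowd demarcations from raters of
   heterogeneous skill;
2. plurality-vote consensus over any assembled crowd;
3. the two agreement metrics (Dice, surface-area error);
4. rater-reliability tracking, per-image top-k crowd selection, and
   learning curves;
5. the study-level analyses: crowd summaries, Mann-Whitney crowd
   comparison, per-photo multi-view spread, and the regression of
   consensus error on within-crowd disagreement.

Patient photographs are not public, so every downstream stage is
exercised on generated data whose *structure* matches the study design;
the headline clinical numbers of the original crowd are not
reproduction targets (they depend on real human raters), only the
qualitative findings are.

## Study structure emulated by the generator

- **Photos and views.** Each simulated "3D photo" is a base 2D image: a
  large wobbly-elliptical skin mask (>= 50% of the frame) containing
  `n_regions` smooth lesion blobs whose total area is steered to a
  target fraction of the skin (hit within +-30%; internally +-15%).
  Views are small rigid transforms (rotation <= `max_rotation`,
  translation <= `max_shift`; nearest-neighbour resampling so masks stay
  boolean and subset relations survive). The label `0_0` is the
  identity view. True 3D reprojection is deliberately not modelled:
  rigid 2D transforms preserve the analytical structure — the same skin
  seen several times with consistent geometry — without a mesh
  dependency.
- **Splits.** `gt_provided` photos (7 views each) may be shown to
  raters as feedback and are the only images used to score rater
  reliability; `gt_withheld` photos (9 views each) form the evaluation
  set, restricted to images with affected skin. The full-scale layout
  (`RunConfig.full_scale()`): 100 affected + 20 unaffected provided
  photos, 79 affected + 161 unaffected withheld photos — 3000 2D images
  in total, 711 of them withheld-affected.
- **Arms and exposure.** Raters are randomized to a high-feedback arm
  (feedback on 1 of every 4 provided cases) or a low-feedback arm (1 of
  every 14). Exposure is logged per rater; by default it does not alter
  skill, because no learning was observed in the task this emulates. A
  `skill_drift` knob (px of jitter change per prior submission) exists
  solely to exercise the learning-curve machinery.

## Rater noise model

Skill is a per-rater record, drawn per arm:

| parameter | meaning | default distribution |
|---|---|---|
| `boundary_jitter_sigma` (px) | vertex noise when tracing a boundary | lognormal, median 2 px, log-sd 0.5 |
| `region_detection_prob` | chance of noticing a lesion region | Beta(8, 2) (mean 0.8) |
| `false_positive_rate` (regions/image) | spurious blobs, Poisson mean | Gamma(2, 0.1) (mean 0.2) |
| `node_budget` | max polygon vertices per region | uniform 10–30 |

A rater traces each detected region's contour with at most
`node_budget` evenly spaced vertices (emulating the coarse node-based
outlines of a touch interface), perturbs the vertices with zero-mean
Gaussian jitter, and may add Poisson-many spurious wobbly blobs inside
the skin. The rasterized polygon union is clipped to the skin mask.
Arms share the same skill distribution by default; the desk-scale
configuration gives the high-feedback arm `jitter_scale = 0.8`,
emulating the training benefit of frequent expert feedback.

Two *image-level* components are shared by all raters of an image,
because real crowds err collectively on hard photos:

- **Detection copula** (`detection_correlation`, default 0.8). A rater
  detects a region iff `Phi(rho*z_region + sqrt(1-rho^2)*z_rater) < p`.
  The marginal detection probability is exactly `p` for every rater —
  the per-rater detection calibration is untouched — but the same
  subtle region tends to be missed by much of the crowd at once. At
  `rho = 1` this becomes a pure conspicuousness-threshold model.
- **Shared extent bias** (`extent_bias_sd`, default 0.15 log-units).
  Each (image, region) draws a radial scale `exp(N(0, sd))` applied to
  every rater's traced boundary: the crowd collectively over- or
  under-extends the same border. This reproduces the sharp-edged,
  lower-specificity boundaries nonexpert crowds draw relative to an
  expert, and it is the error mode that makes within-crowd disagreement
  a poor predictor of consensus accuracy: plurality voting cannot
  remove a bias the whole crowd shares, and the crowd's spread carries
  no information about it. Both components default to off/neutral at
  the single-demarcation function level and are wired in by the study
  simulator from the run configuration.

Randomness is reproducible by construction: one master seed, with each
(rater, image) pair's stream derived by hashing
`(seed, rater_id, image_id)` (BLAKE2, reduced below 2^31), so any
single demarcation is identical regardless of generation order.

## Consensus, metrics, analyses

- **Plurality vote.** Per pixel, the count of raters who marked it;
  the consensus keeps pixels with `count / n_raters >= 0.5`. The
  threshold is against the full crowd size, not the raters who marked
  anything, and exact halves in even crowds are *included* — "50% or
  more" read literally. The threshold is config-exposed for sensitivity
  analyses; 0.5 is the study-faithful value.
- **Dice** `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 (agreement on
  absence — only reachable on edge fixtures, since evaluation is
  restricted to affected images).
- **Surface-area error**: absolute difference of affected-area
  percentages, with the *skin mask* (not the frame) as denominator.
  It is a pure area metric — invariant to where pixels are marked —
  which is exactly why it complements Dice.
- **Reliability.** Per-rater mean Dice (default) or mean surface-area
  error over their `gt_provided` demarcations. Which score the original
  study used for "best performers" is unknown; both are implemented and
  the ranking metric is a config option. Top-k selection applies the
  global ranking to each image's available raters (per-image is about
  availability, not re-scoring); unscored raters are eligible but rank
  last, and ties break toward earlier enrollment.
- **Learning curves.** Each rater's first `horizon` demarcations of
  affected withheld images, in their own submission order, binned into
  `horizon/window` windows (defaults 100/20); raters short of the
  horizon are excluded. The study runner adapts the horizon downward
  (largest multiple of 5 any rater reached, capped at 100) so
  desk-scale studies still produce curves.
- **Crowd comparison.** Mann-Whitney U with midranks; exact two-sided p
  by full enumeration of rank assignments for combined n <= 12
  (p = 2·min(P(U<=u), P(U>=u)), capped at 1), otherwise the normal
  approximation with tie and continuity corrections. The enumeration
  cut-off balances fidelity and runtime; a full-scale evaluation set
  always uses the approximation, as standard.
- **Disagreement vs accuracy.** Per photo: x = sample SD (n-1) of
  individual raters' surface-area fractions pooled over the photo's
  views (per-view SDs averaged is a config alternative); y = the median
  (config: mean) over the photo's views of the consensus surface-area
  error; ordinary least squares of y on x. The view reduction is a
  package choice — the original analysis does not state one — with
  median preferred for robustness.
- **Summaries.** Median, IQR as 25th/75th percentiles with linear
  interpolation (stated because box-plot conventions differ), and mean.

## The null experiment for disagreement-vs-accuracy

The claim under test is *negative*: within-crowd disagreement does not
predict consensus error. A valid null condition must not smuggle in a
common cause, and two were identified and excluded by design:

1. Both axes are absolute percentages of skin, so varying lesion size
   inflates both together. The null condition fixes lesion count and
   coverage across photos (2 regions, 15% of skin).
2. Partial region-detection events put a photo simultaneously high-SD
   (some raters miss a region) and high-error (the consensus drops it).
   The null condition uses certain detection; region drop-outs are a
   separate, rare failure mode covered by the detection-calibration
   tests.

Under that design — an identical-skill crowd of 17 over 40 size-matched
photos, with the shared extent bias driving consensus error — the
fitted R² is below 0.1 in roughly 95% of seeded replicates. Without the
design controls, the simulation *does* show a strong R², which is worth
remembering when interpreting such plots on real data: absolute-scale
metrics correlate with anything that also scales with lesion size.

## Numerical choices

- **Rasterization.** A pixel belongs to a polygon iff its center
  `(row + 0.5, col + 0.5)` lies inside under the even-odd rule;
  overlapping polygons union. Implemented as a vectorized crossing-number
  test restricted to each polygon's bounding box, and pinned against
  exact pixel counts and `matplotlib.path` on convex fixtures. All
  coordinates are 0-based `(row, col)`, row 0 at top.
- **Contour tracing** uses `skimage.measure.find_contours` at level
  0.5, shifted by +0.5 into the pixel-center frame.
- **View transforms** use `scipy.ndimage.affine_transform` with
  nearest-neighbour interpolation; a transform losing more than 5% of
  skin pixels is rejected.
- **Degenerate inputs.** Empty demarcations are valid (empty polygon
  list, all-false mask). Consensus requires at least one demarcation.
  Regression requires at least 3 photos. Constant-y regressions report
  slope 0, R² 0.
- **Determinism.** Dataset writes are byte-stable (sorted iteration,
  fixed CSV schemas); demarcation masks are not stored but re-rasterize
  exactly from their polygon loops under the fixed rasterization rule.

## Problem sizes

`desk_scale()` — the configuration the analysis drivers and heavier
tests use — is structurally identical to the full layout at reduced
size: 64×64-px images, 8+2 provided photos × 7 views, 6+2 withheld
photos × 9 views (142 images, 54 evaluation images), arms of 20/24
raters with per-image quotas 8/12, four crowds (high r=8, low r=8,
low r=12, low top-5). Replicated experiments use 48×48-px geometry:
skill-contrast pools of 5 low-jitter (sigma=1 px) vs 12 high-jitter
(sigma=6 px) raters over 30 provided + 8 withheld images (30
replicates); the homogeneous null over 40 photos (20 replicates); and
learning curves for 5 raters over 100 affected images (3 replicates).

## Limitations

- Skin and lesions are abstract blobs: no texture, colour, skin-type
  appearance, or photographic effects; nothing here validates human
  perception, only the analysis machinery downstream of demarcations.
- Views are 2D rigid transforms, not true 3D reprojections, so
  view-to-view variation is geometric only.
- The rater model is invented (the emulated study published no
  generative model of rater behaviour); its shared-difficulty
  components were designed to reproduce the qualitative structure of
  crowd errors, not fitted to data.
- The app's training/qualification step is not modelled (its threshold
  is unpublished); simulated raters are "qualified" from the start.
- Passing tests demonstrate correctness of consensus, metrics,
  selection and analyses under the stated noise model — they do not
  certify performance of real crowds on real photographs.
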