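# Methods

## The decision model

The biomarker is a per-patient count `x` of whole-slide tiles classified
TFF3-positive. The positive class is *clinically relevant* Barrett's
oesophagus, defined from the Prague endoscopy measures as C ≥ 1 cm or
M ≥ 3 cm; everything else (short-segment BO, IM of the gastro-oesophageal
junction) is *focal*. The model is an unpenalised maximum-likelihood
logistic regression of that label on a monotone transform of the count,
`log1p` by default (raw counts available via `feature_transform=
"identity"`). Because the feature is one-dimensional and the transform
monotone, the fitted model is fully characterised by the tile threshold

    x* = transform⁻¹(−β₀ / β₁),

the count at which the predicted probability crosses 0.5. Predictions at
exactly 0.5 go to the relevant class: for a screening test the costly
error is the miss, so ties resolve conservatively. For clinical use the
threshold is floored to an integer (`discrete_threshold`), matching how a
count cut-off would be operated.

Two degeneracies are handled explicitly rather than silently. Under
complete separation (no count overlap between classes) the likelihood
diverges; the fit then reports the midpoint of the empirical count gap as
the threshold, flags the model as `separated`, and warns. A fitted slope
≤ 0 (count not positively associated with relevance) also warns, since
the threshold interpretation presumes a positive association.

Cross-validation is stratified k-fold (default k = 5) with shuffling
under a caller-supplied seed; each fold's model is fitted on the
remaining folds and yields held-out metrics plus its own threshold. The
summary rows are the plain mean and sample SD (ddof = 1) over fold
values, so they recompute exactly from the fold rows. Transfer to an
external cohort refits nothing: the model trained on the full training
cohort is applied as-is, which is precisely the no-recalibration claim
the triage arithmetic depends on.

Class-balanced accuracy is the mean of the two per-class recalls
(sensitivity and specificity), preferred over raw accuracy because the
cohorts are imbalanced. Per-class precision/recall/F1 come from the
confusion counts; metrics with empty denominators are reported as NaN,
not zero.

## Tiling

Pixel coordinates are 0-based and all rectangles half-open
([x0, x1) × [y0, y1)), which makes tile areas and disjointness exact in
integer arithmetic. Training tiles come from polygon annotations: the
annotation's axis-aligned bounding box (floor on lower bounds, ceil on
upper) is gridded row-major with non-overlapping tiles anchored at the
box's top-left corner — partial tiles at the right/bottom are discarded,
never padded — and a tile is retained iff
`area(tile ∩ polygon) / area(tile) ≥ 0.66`, computed by exact polygon
clipping (shapely). The 0.66 retention fraction and the 400 px tile edge
are configuration with those defaults. Anchored tiling is the simplest
reading of "as many non-overlapping tiles as possible"; searching grid
offsets to maximise the retained count is deliberately out of scope.
Tiles claimed by several overlapping annotations are deduplicated by
origin so per-slide counts are counts of unique tiles. Inference-time
counting uses the same grid over the full raster, since no annotations
exist at screening time; whether the original analysis counted within
annotations or over the whole slide is not documented, so both are
exposed and whole-slide is the default.

The pixel-membership convention is centre-in-polygon: pixel (i, j)
belongs to a polygon iff the point (j + 0.5, i + 0.5) is covered by it.
The exact-clipping overlap and this rasterised estimate agree within
2/edge per tile, which the tests verify on random fixtures; tiles whose
rasterised overlap sits within that resolution band of the 0.66 cut-off
are the only ones on which the two retention decisions may differ.

The slide's stated physical scale is internally inconsistent in the
source material (400 px is quoted both as 200 µm and 100 µm);
`microns_per_pixel` is therefore carried as provenance-only
configuration and nothing computes with it.

## Statistical machinery

Gland counts from slides 2 and 15 yield four per-patient parameters:
each slide's count, their average, and their maximum. The latter two are
deterministic functions of the former — they add no information, only a
different summary. Group variances differ, so group means are compared
with Welch's t-test: `se = sqrt(s1²/n1 + s2²/n2)`, degrees of freedom by
Welch–Satterthwaite, two-sided p, and a 95 % CI of `diff ± t(df)·se`
(the published CIs reproduce from the printed group summaries under
exactly this construction). The data path computes summaries and
delegates to the summary path, so the two cannot drift apart. Levene's
test defaults to mean-centred deviations (the original form) with the
median-centred Brown–Forsythe variant available. p-values below 0.001
are reported as "<0.001" in formatted output.

AUROC is computed by the tie-corrected Mann–Whitney rank formula; for a
univariate logistic score with positive slope this equals the raw
feature's AUROC (asserted in tests, since the score is a strictly
increasing transform of the feature). The confidence interval uses
DeLong's variance from placement values with a normal quantile, clipped
to [0, 1]; the interval construction used in the source analysis is not
stated, and DeLong is the field's default. The DeLong computation is
written here because no installed package provides it.

## The synthetic-data generator

The generator's job is to produce cohorts with the *statistical shape*
the analysis assumes, so that pipeline claims can be tested end to end:

- **Class prevalence.** Bernoulli with default 0.595 (surveillance-like,
  `BEST2_LIKE`) or 0.296 (screening-like, `BEST3_LIKE`).
- **Prague lengths.** Class-conditional so the label derived from (C, M)
  always equals the drawn class: relevant patients get M = 3 + an
  exponential tail (scale 3 cm) capped at 15 cm and C = max(0, M − gap)
  with an exponential gap (scale 1.5 cm); focal patients get M = 0 with
  probability 0.35 (IM of the junction) or 1–2 cm, with C clamped to 0.
  Lengths round to whole centimetres, as endoscopy reports them.
- **Tile counts.** Negative binomial with log-mean `1.0 + 0.32·M` and
  dispersion 2.5. No generative count model is published, only
  histograms and rank correlations; over-dispersion reproduces the heavy
  right tail, and the slope/dispersion defaults were chosen so the
  cohort-level Spearman(count, M) sits near 0.75, inside the 0.65–0.85
  band that brackets the reported correlations. They are fixed study
  conditions, not tuning knobs.
- **Gastric-control counts.** Negative binomial (mean 20, dispersion 5),
  independent of length by construction. QC failures — modelling sponges
  that never reached the gastric cardia — get a zero gastric count; the
  default failure rate is 2 %.
- **Gland counts.** Per class and slide, a normal draw truncated at 0
  and rounded to an integer. Truncation shifts a naive normal's mean
  upward, so the underlying (µ, σ) are moment-matched numerically so the
  *post-truncation* mean equals the configured class mean exactly and
  the SD as closely as the family allows. A zero-truncated normal cannot
  have SD > mean (the exponential limit), so the focal-class SD targets
  (e.g. 3.09 against mean 2.86) are approached, not hit; class means are
  exact, which is what the group-difference statistics consume.
- **Seeding.** One cohort seed feeds a `numpy.random.SeedSequence` whose
  spawned children drive class draw, lengths, counts, gland counts,
  gastric counts and QC independently — changing one sub-model leaves
  the other streams untouched, and a fixed seed is bit-reproducible.

`simulate_threshold_cohort` is a second generator for experiments that
need a known decision boundary: counts are drawn as above, then labels
are Bernoulli with `P(relevant | x) = σ(s·(log1p x − log1p t*))`,
default t* = 16 and steepness 6 (steep enough that the boundary is
sharp at cohort sizes of a few hundred, soft enough that classes
overlap and the logistic fit is regular). Prevalence shifts between
cohorts come from the length distribution, never from the conditional
label model — mirroring how a surveillance and a screening cohort differ.

Slide fixtures (`simulate_annotated_slide`) paint non-overlapping random
convex polygons (TFF3-coloured and gastric-coloured) on a pale
background, with optional Gaussian pixel noise, and return the raster,
the generating polygons and a pixel-exact label mask; the raster is
painted *from* the rasterised polygons, so image, mask and annotations
agree by construction and the mask can serve as ground truth for tiling
and counting oracles. The reference tile classifier is a pure colour
rule (fraction of pixels within a per-channel tolerance of the target
colour ≥ 0.5).

What the generator does **not** emulate: real stain physics and
scanner artefacts, CNN classification errors (the reference classifier
is deterministic), spatial correlation of IM within a slide, the joint
distribution of gland counts with tile counts (they are conditionally
independent given class), and the exact count histograms of the trials.
Passing tests therefore demonstrate that the *machinery* — tiling
geometry, counting, threshold estimation, transfer, and the statistical
formulas — is correct under the assumed structure; they do not re-verify
the clinical numbers on the trial data, which would require the original
scans and tables.

## Problem sizes and numerical choices

Simulated cohorts default to n = 529 (training-like) and n = 158
(screening-like), the sizes of the source cohorts; replicate-based
checks use 20 replicates for threshold recovery and 10–20 seeds for
monotonicity checks. Slide fixtures in tests are 512 × 384 px with
64 px tiles — the geometry scales linearly, so small fixtures exercise
the same code paths as full-size slides. Logistic fits run to
convergence with statsmodels' defaults (capped at 200 iterations);
thresholds are reported to one decimal and metrics to two in formatted
reports, with SDs of thresholds to two. Report rounding is applied only
at the I/O layer — in-memory values are never rounded.

## Known limitations

- The QC flag is an input; detecting gastric cardia mucosa from H&E
  images is out of scope.
- The CNN tile classifier is out of scope; any pure
  pixels-to-label callable satisfies the contract, and only the colour
  reference classifier ships.
- Pyramidal WSI formats are not read; rasters are plain PNG/TIFF-size
  images.
- The threshold model is univariate by design; multivariable risk
  models and survival analysis are non-goals.
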