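# Methods

`wmiquant` re-implements, as a tested and reusable pipeline, the
quantitative neuropathology workflow used to grade hypoxic-ischemic white
matter injury (WMI) in the preterm-equivalent fetal brain: a
histogram-reflection area-fraction estimator for immunofluorescence
(GFAP astrogliosis, Iba-1 microglial activation), optical-fractionator
stereology for O4-labelled pre-oligodendrocyte densities, ordinal injury
scales, and the accompanying nonparametric statistical battery.  Because no
per-animal raw data are published for these endpoints, every estimator is
exercised on synthetic inputs with known ground truth; the reported
group summaries serve as the default simulation conditions.

## Area-fraction estimation (`image_quant`)

**Model.** A stained micrograph is background `b(x)` (slowly varying
illumination) plus noise plus bright specific staining on a subset of
pixels.  The area fraction (AF) of a region of interest is the proportion
of its pixels attributable to staining.

**Procedure.**

1. *Rolling-ball background subtraction* (default radius 150 px): the
   background is the grayscale opening of the image by a spherical-cap
   structuring element with heights `sqrt(r^2 - dx^2 - dy^2)`; the opened
   surface is subtracted.  The opening never exceeds the image, so the
   result is nonnegative.  The erosion/dilation pair is a numba-compiled
   brute-force kernel with reflected borders (identical, pointwise, to
   `scipy.ndimage` grey morphology with the same nonflat element, which the
   test suite uses as an oracle; the scipy route is several-fold slower at
   large kernels).  Note the cap is nonflat: a raised plateau of width `w`
   is flattened only up to a penetration of `r - sqrt(r^2 - (w/2)^2)`
   (≈0.08 intensity units for a 10 px feature under a 150 px ball).
2. *ROI histogram*: equal-width bins over `[0, max]` (default 256 bins;
   half-open bins, last closed).
3. *Background peak*: the histogram mode is found on the 3-bin moving sum
   of the counts.  Because specific staining is bright-on-dark, when the
   histogram carries more than one mode of comparable height (heavy
   staining approaching half the ROI makes it bimodal) the
   lowest-intensity mode with prominence at least half the tallest is
   taken.  The peak is then the count-weighted mean centre of the mode bin
   and its two neighbours, and — by default — refined to the midpoint of
   the mode's half-height crossings.  The refinement exists because a
   histogram-mode estimator converges only at ~N^(-1/5): at desk-scale
   images (256x256 = 65,536 px) its jitter alone contributes ~0.03-0.04
   mean absolute AF error, while the half-height midpoint uses the steep
   flanks of the (symmetric) background mode and converges at the
   parametric rate.  It is insensitive to the exact half level (lowering
   the level moves both crossings outward together), is exact for
   delta-like histograms (noiseless images), and falls back to the
   centroid when a flank never crosses.  `peak_refine="centroid"` restores
   the bare three-bin estimate.
4. *Reflection*: the counts of all bins strictly below the peak, plus half
   the count of the bin containing the peak, are doubled — the background
   distribution is assumed symmetric about its peak, while stained pixels
   contaminate only the bright side.  The result estimates the total
   number of background pixels.
5. *AF*: labelled area = `max(0, total - background)`; AF = labelled /
   total.  The clamp keeps AF a proportion when a heavy low tail pushes
   the doubled background estimate past the ROI size.

**Parameters.** `ball_radius_px` (150 default; it must be much larger than
stained structures and is quoted for full-resolution 10X montages — the
synthetic 256 px tiles in this package use 50 px, the same
radius-much-greater-than-feature regime for features of ≤ ~12 px radius);
`n_bins` (256); `background_side` (`"low"`; flip for inverted stains);
`mode_prominence` (0.5 — a competing mode must reach half the tallest
mode's prominence to be considered; this also rejects the spike of
exact-zero ball-contact pixels that small radii produce).

**Accuracy.** On synthetic tiles spanning AF 0-0.5 with contrast = 5 noise
SD, the mean absolute recovery error is below 0.02 (typically ~0.007);
noiseless two-level images are recovered exactly.  The doubling step
assumes a symmetric background residual; the opening floor introduces a
mild skew that leaves a small positive bias (~0.006) at AF = 0.

## Optical-fractionator stereology (`stereology`)

**Design** (defaults are the study geometry): sampling grid 296.6 x
277.2 um with a uniform-random offset; 85 x 85 um counting frame per grid
cell; 3 um guard zone below the section surface; 25 um optical dissector;
section thickness recorded at every 5th site, used only for the QC
invariant `thickness >= guard + dissector`.

**Counting rules.** A cell is counted when its (x, y) satisfies
`x0 < x <= x0 + w`, `y0 < y <= y0 + h` (left/bottom edges and their
extensions forbidden; right/top inclusive) and its depth satisfies
`guard <= z < guard + dissector`.  On tiling designs these half-open rules
assign every cell to exactly one frame, making a full tiling equivalent to
an exhaustive count — a property the tests verify, along with
translation-invariance of the expected count and unbiasedness of the
density over replicate Poisson fields at 15,000-30,000 cells/mm^3.

**Estimates.** Density = sum(Q) / (n_sites x frame area x dissector
height), converted to cells/mm^3; intact and pyknotic (degenerating)
cells are tallied separately and the pyknotic percentage is
`100 * Q_pyk / (Q_pyk + Q_intact)`.  Precision is summarised by a
coefficient of error computed as (SD/sqrt(n))/mean over per-site counts —
the equal-sized-unit reduction of the Scheaffer-Mendenhall-Ott
survey-sampling CE.  The full ratio-estimator form is not needed for
equal-size frames.  Densities use the nominal dissector height, not
measured thickness; no shrinkage correction is applied.  Planar
estimators: `field_density` (counts over n sampled fields, cells/mm^2)
and `exhaustive_density` (total count over ROI area).

## Ordinal scales (`scoring`)

White-matter necrosis per section: 0 (none), 1 (1-25%), 2 (26-50%),
3 (>50%).  Real-valued percents map with exactly 0 -> 0 and half-open
bands `(0,25] -> 1`, `(25,50] -> 2`, `(50,100] -> 3`, so "greater than
50%" starts strictly above 50.  Gray matter uses a 4-point composite
(0 normal .. 3 extensive/translaminar necrosis) combined across H&E and
Iba-1 stains; the combination rule is configurable (`max`, the default
worse-stain reading, or rounded `mean`).  Section scores are averaged per
region and severe pathology is an average of 2 or greater (inclusive).
Severity averaging is per stain with sections averaged; the per-group
share of severe animals is reported among all severe animals and sums
to 100% when defined.

## Statistics (`stats`)

Group comparisons use the tie-corrected Kruskal-Wallis H with a
chi-square reference on k-1 df (a completely constant endpoint reports
H = 0, p = 1).  When the omnibus test rejects at alpha = 0.05, two-sided
Mann-Whitney U tests run for the configured pairs with Bonferroni
adjustment `p_adj = min(1, m p_raw)`; m defaults to all 6 pairs among 4
groups (the conservative reading — the original report does not state m).
The U test is exact (full enumeration, via scipy) when the pooled sample
is tie-free and `n_a * n_b <= 400`, otherwise the tie-corrected normal
approximation with continuity correction is used.  Spearman's rho is
Pearson on mid-ranks; for n <= 9 the two-sided p comes from exhaustive
permutation, otherwise from the t approximation.  Zero-variance inputs
are flagged undefined rather than an error.

The twin structure is checked per endpoint with a fixed-effects block
decomposition (treatment group entered first, ewe second; Type I
sequential SS, via statsmodels).  Two summaries are reported: `r2_ewe =
SS_ewe / SS_total` (the raw SS share — note that with twins the ewe
factor holds roughly half the post-treatment degrees of freedom, so this
is ~0.45 even under the null) and `icc_ewe`, a method-of-moments
variance-component intraclass correlation that is near zero when litter
membership carries no information, alongside the ewe term's F-test p.  A
random-intercept likelihood fit is out of scope.  When every animal is a
singleton there is no within-ewe information and the check raises; with
only one informative ewe the result is flagged underpowered.

## Synthetic data (`synthetic`)

*Images*: background level + two low-frequency sinusoidal illumination
components + additive Gaussian noise on a 16-bit scale; foreground as
random disks ("blob", somata-like) or random thick polylines ("filament",
process-like), each shape's area capped so shapes are added until the
true mask fraction is within 0.004 of target.  Defaults: 256 x 256 px,
0.645 um/px, background 2000, gradient amplitude 300, noise SD 120,
contrast 600 (5 SD).  Not modelled: shot noise (the CCD montages are
treated as Gaussian-limited), anti-aliased structure edges, out-of-focus
light, montage stitching seams — so passing recovery tests show
correctness of the estimator under its own model assumptions, not
robustness to every acquisition artifact.

*Cell fields*: homogeneous Poisson point process in a slab (defaults
1200 x 1200 x 40 um in the pipeline), each cell independently pyknotic
with probability 2% (the observed 1-5% range).  Clustering and section
compression are not modelled, so unbiasedness tests certify the counting
geometry, not robustness to inhomogeneity.

*Cohorts*: Control n=5, Early HI n=5, Late HI n=6, recurrent HI n=6, with
twins paired across arms as in the experimental design (control with
early HI; late HI with recurrent HI).  Endpoint value = group mean + ewe
intercept + residual; the group means/SDs default to the study's reported
group values for GFAP AF, Iba-1 AF, Olig2 density, O4 density,
pyknotic %, and AC3 density.  `ewe_sd` is expressed as a fraction of each
endpoint's total SD (endpoints span four orders of magnitude, so an
absolute shared SD would be meaningless); default 0, since the original
analysis found the ewe term uninformative.  A per-animal shared severity
factor with loading 0.7 on every endpoint's residual induces the positive
cross-endpoint correlation observed in the study (within-group r ~ 0.5,
cohort-wide rank correlation considerably higher once group separation is
added); the loading is not identifiable from published summaries and is
configurable.  Ordinal section scores discretise a latent severity
(group-level mean/SD mirroring the reported score summaries, per-section
jitter SD 0.3, rounded and clipped to 0..3).

## Pipeline and reproducibility (`pipeline`, CLI `wmi-quant`)

`run_all` simulates a cohort, renders one tile per group at the group's
astrogliosis level and re-estimates its AF, simulates one cell slab per
group at the group's O4 density and runs the fractionator, and writes the
score report, the statistical battery, and a per-endpoint-per-group
summary table.  All stages write plain CSV/JSON/YAML/TIFF/PNG and are
byte-reproducible for a fixed seed (sub-seeds via `numpy.random
.SeedSequence`).  The pipeline default tile is 256 px with a 50 px ball
(desk-scale geometry); the published full-montage radius of 150 px is the
library default for real images.

## Numerical choices and degenerate inputs

- Histogram mode ties resolve toward lower intensity (stable argmax).
- The peak-containing bin contributes half its mass to the background
  side regardless of which side of the peak its centre falls on.
- An empty sampling grid (ROI smaller than one grid cell) warns and
  returns no sites; density estimation with zero sites is an error.
- CE is undefined (None) for a zero mean count; pyknotic percentage is
  undefined when no cells were counted.
- Mann-Whitney on two identical samples reports U = n_a n_b / 2, p = 1.
- Bonferroni never lowers a p-value and caps at 1.

## Known limitations

- The AF estimator's symmetric-background assumption is mildly violated
  by the opening floor; the residual bias (~+0.006 at AF 0) is well under
  the recovery tolerance but not zero.
- The spherical-cap opening penetrates plateaus slightly (see above);
  ImageJ-style intensity rescaling of the ball is not implemented.
- Stereology operates on point data (simulated or human counts), not on
  images; soma extent and over-/under-projection are not modelled.
- The ewe check is a fixed-effects decomposition, not a mixed model.
- Exact Mann-Whitney switches to the normal approximation in the
  presence of any tie, which is conservative for tiny samples with ties.
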