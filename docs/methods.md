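# Methods

This note documents the models implemented in `adiporisk`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducibility.

## Adipocyte morphometry

Adipocytes appear on H&E as bright lipid vacuoles separated by thin
eosinophilic membranes.  Segmentation thresholds grayscale luminance
(Otsu by default; a fixed threshold is available for cross-batch
reproducibility), fills holes, optionally splits merged cells by a
distance-transform watershed, removes border-touching objects, and drops
any object overlapping the exclusion zone within 500 µm of a provided
duct mask (lesion-adjacent fat is remodelled and is not representative of
the bulk adipose compartment).  Contours are extracted at sub-pixel
precision as the 0.5 iso-contour of the binary mask (marching squares);
coordinates are pixel-centred, x right / y down, and converted to µm by
the microns-per-pixel calibration.  All downstream lengths are exactly
linear in the calibration, so diameters scale by k and areas by k² when
the calibration is scaled by k.

**Chord measurement.**  Each object's diameter summary uses 18 probing
lines through the polygon centroid at 10° increments.  A "chord" is
defined as the *total in-object length* of the probing line — identical to
the extreme-to-extreme chord for convex shapes and still well defined for
mildly irregular contours.  The object diameter is the median of the 18
chords (mean of the 9th and 10th order statistics).  Shape gates:
circularity is the isoperimetric quotient 4πA/P², regularity the min/max
chord ratio.  An object whose centroid falls outside its own contour is
flagged unmeasurable and excluded.

**QC defaults.**  Median diameter ≥ 30 µm (separates mature adipocytes
from debris; applied to the median diameter, not to individual chords),
circularity ≥ 0.6, regularity ≥ 0.4.  The shape cut-offs are declared
package defaults — commercial vacuole modules do not publish theirs — and
are configurable and logged per rejection with machine-readable reasons.
On marching-squares contours a rasterised circle measures circularity
≈ 0.90 (the staircase inflates the perimeter), crescents ≈ 0.4; the 0.6
default separates these with margin on both sides.

**Patient summary.**  Per-patient scores are the 75th percentile of the
kept objects' median diameters and areas, using linear interpolation
between closest ranks (the numpy default).  The upper quartile deliberately
weights the large, unambiguously intact cells.  A patient with zero kept
objects raises `NotAssessableError` rather than emitting a profile.

## Tissue composition

A random forest (100 trees, seeded, deterministic) on hand-crafted tile
features: per-channel mean/sd, grayscale mean/sd, bright and dark pixel
fractions, and a first-difference roughness term.  Tiles are 64 px with
stride equal to tile size; ragged edge tiles are classified with their
true extent.  Area percentages are computed over the three tissue classes
only; background (glass) is excluded from the denominator, so the adipose
percentage is a pure ratio and calibration-invariant.  The feature set is
deliberately simple: the contract is accurate *area fractions* on
desk-scale rasters, not a production histology classifier.

## Crown-like structures

CD68 IHC rasters are separated with the standard
hematoxylin/eosin/DAB optical-density matrix; the DAB channel (clipped at
zero) is thresholded at 0.15 OD by default — about seven standard
deviations above the stain-noise floor of the synthetic renderer, so a
DAB-free image yields an empty mask — and restricted to tissue (total
OD > 0.02).  For each adipocyte the peri-cellular annulus (20 µm wide,
the scale of one macrophage rim) is split into 36 angular bins around the
centroid; a bin is positive when ≥ 10% of its pixels are CD68-positive,
and the crown coverage is the positive fraction of occupied bins.  An
object is called a CLS at coverage ≥ 0.33.  The morphological definition
("surrounded by a rim") has no published numeric equivalent; both the
annulus width and the coverage threshold are configurable and logged.

Known limitation: in densely packed tissue a rim around one cell also
occupies the shared septum, so its neighbour's annulus picks up positive
bins along the shared boundary.  At the default thresholds this can
inflate neighbour coverage in heavily inflamed, tightly packed fields;
count-exactness is therefore only guaranteed when rims are separated by
more than the annulus width, and the synthetic validation uses such
layouts.  Patient-level density sums CLS counts and adipose areas across
all of a patient's sections before dividing (multi-block protocols), and
is dichotomised at ≥ 5 CLS per 10 cm².

## Conditional logistic regression

With one case per matched set the conditional likelihood
`Π_sets exp(x_case·β)/Σ_{j∈set} exp(x_j·β)` removes all set-level effects
(here: age at diagnosis, absorbed by the matched design).  The
implementation:

- Newton-Raphson with step-halving; convergence at max |gradient| < 1e-8,
  cap 50 iterations; non-convergence raises with the last iterate.
- Set-level complete-case analysis: a record with a missing model
  covariate drops its whole set.
- Identifiability screen on within-set-centred covariates: a term with no
  within-set variation anywhere raises; a term collinear with earlier
  terms is dropped with a warning (order-preserving Gram-Schmidt, so the
  first-named term wins).
- Standard errors from the inverse observed information; 95% CIs use
  z = 1.959964; p-values are likelihood-ratio based (χ² upper tail, df =
  parameter-count difference; df 0 ⇒ p = 1).
- |log-OR| > 15 flags probable separation; no penalisation is applied.
- Continuous terms can be reported per scaled unit (per 10 µm, per 10³
  µm², per 10%) via the `scales` argument — raw rescaling, no
  standardisation.

The suite cross-checks coefficients, standard errors and log-likelihood
against an independent conditional-likelihood implementation
(statsmodels' `ConditionalLogit`) and against the paired-data closed form
(OR = n10/n01).  The crude 2×2 odds ratio is provided as an explicitly
different quantity: with exposure related to the matching variable the
crude and conditional estimates differ, and the tests document that
difference rather than asserting any equality.

Quartile coding pools cases and controls, cuts at the interpolated
25/50/75 percentiles, and assigns half-open [low, high) intervals, so 276
distinct pooled values occupy 69/69/69/69 and a value equal to a cut
point belongs to the upper quartile.  Menopausal-status proxies from age:
< 45 premenopausal, 45–<55 perimenopausal, ≥ 55 postmenopausal.
Multivariable model building screens candidates by univariate LR p ≤ 0.1,
then optionally LR-tests pairwise interactions between included main
effects under the same entry rule; all decisions are returned in an
inclusion log.  Group comparisons wrap the standard two-sided
Mann-Whitney, Kruskal-Wallis, t, ANOVA and Shapiro-Wilk tests; Spearman's
ρ is reported with a Fisher-z 95% CI.

## Expected cumulative incidence

Rate tables carry age-specific event and all-cause mortality rates per
person-year in 1-year bands.  Over each step the exact
piecewise-constant-hazard competing-risk solution is used
(ΔCI = S·λ/(λ+μ)·(1−e^{−(λ+μ)Δt}), S multiplied by e^{−(λ+μ)Δt});
annual steps by default, and the step exactness means refining the grid
changes nothing while rates are constant within bands.

Subgroup curves take each group's odds ratio as a rate ratio on the
cause-specific event hazard — a rare-event approximation, stated as such —
with mortality left identical across groups.  At every step a baseline
scaling c is solved (Brent's method) so that the prevalence-weighted group
increments reproduce the marginal increment; the prevalence-weighted mean
of the group curves therefore equals the marginal curve by construction,
and raising one group's rate ratio strictly raises its curve while the
re-solved baseline pushes the others down.

## Synthetic data: what it emulates, and what it does not

**Images.**  Cells are placed by random sequential packing of disks with a
pairwise gap equal to the membrane thickness, then rendered as smooth
polygons (low-order radial harmonics, ≤ 4% amplitude) on an
eosin-coloured background: bright interiors, pink septa, optional
collagen-textured stroma band.  The gap constraint makes every polygon
disjoint by construction, so the exact polygon area and 18-chord median
are recorded as ground truth per object.  Packing is refused above 52% of
the usable canvas (random sequential packing jams near 55%), raising an
explicit error rather than silently truncating.  Artifacts are crescents
(disk minus offset disk: circularity ≈ 0.4, very uneven chords), debris
are sub-30 µm disks — each class fails exactly the QC gate it is meant to
exercise.  Defaults: 2048×2048 px at 0.5 µm/px (a 1.05 mm² field), 120
cells, lognormal diameters with median 65 µm and log-sd 0.25 (a mature
breast adipocyte population whose upper quartile sits near 80–90 µm),
4 µm septa.  Not emulated: staining variation, blur/vignetting, nuclei,
duct morphology (duct masks are synthetic inputs), whole-slide scale.
Passing tests therefore demonstrate algorithmic correctness on idealised
tissue, not robustness to real-slide artefacts.

**CD68 overlays.**  Flagged cells receive an annular rim (15 µm wide) over
a configurable angular fraction of their boundary, clipped to the septal
stroma (never inside a vacuole).  Rendering mixes hematoxylin and DAB
optical densities with Gaussian stain noise (sd 0.02) and converts to RGB
through the standard stain matrix, so colour deconvolution is exercised
end to end.  Cell placement keeps a 16 µm edge margin so rims never clip
the canvas.

**Cohorts.**  A full cohort (default 6× the requested number of sets) is
simulated with exponential event times under proportional hazards
(baseline 0.02 events/person-year at mean covariates, 15-year follow-up,
diagnosis ages N(57, 10²) truncated to 30–88).  Cases are events inside
follow-up; controls are drawn at each case's event time from the risk set
with baseline age within half the matching window of the case's age, so
the within-set age spread never exceeds the window (0.5 years by
default).  This incidence-density sampling makes the conditional-logistic
estimand equal the simulated log hazard ratios.  Default covariates: a
binary marker with prevalence 0.6 and true OR 3.70, and a continuous
size covariate N(6400, 1600²) µm² with an 80 µm²/year age trend and true
OR 1.17 per 10³ µm² — an age-confounded exposure that the matching must
(and does) absorb.  Controls per set are drawn uniformly from {1, 2}; the
matching-ratio distribution in real registries is rarely reported, so this
is a declared modelling choice.  Cases whose age-matched risk set is too
small are skipped; the generator raises if the requested number of sets
cannot be formed.  Not emulated: staggered calendar entry, loss to
follow-up, measurement error in covariates.

**Rate tables.**  One row per 1-year age band; constant or linear
incidence, constant or Gompertz (b = 0.09/year) mortality.  These are
deliberately stylised stand-ins for national registry rates.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate at sizes chosen for
desk-scale determinism: 100-cell images for segmentation recovery (≥ 98
recovered, sizes within 2% of polygon truth for cells ≥ 40 µm), 200
replicates of 1000 matched sets for bias (< 0.05 on the log scale at true
OR 2.75) and Wald coverage (93–97%), and 500 null replicates for LR
type-I error (3–7% at α = 0.05).  A 2000-replicate calibration run during
development measured a type-I error of 5.5% with p-values indistinguishable
from uniform (KS p = 0.41).
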