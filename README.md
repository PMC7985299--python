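# adiporisk

Breast adipocyte morphometry and matched case-control risk modelling for
studies of ductal carcinoma in situ (DCIS) outcomes.

Most DCIS lesions never progress to invasive cancer, so prognostic markers
that separate hazardous from indolent disease are badly needed.  One
candidate marker family lives in the tumour microenvironment: hypertrophic
breast adipocytes and inflamed white adipose tissue (crown-like structures,
CLS).  This package implements the full analysis chain needed to evaluate
such markers in an age-matched nested case-control design:

1. **Morphometry** — segment intact adipocytes (bright lipid vacuoles) on
   calibrated H&E rasters and measure each object with 18 chords through
   its centroid at 10° increments; the object's diameter is the median
   chord, and each patient is summarised by the 75th percentile of their
   per-adipocyte diameter and area distributions (diameter⁷⁵ᵗʰ, area⁷⁵ᵗʰ).
   Objects with median diameter < 30 µm are excluded as debris, and
   roundness/regularity gates (4πA/P², min/max chord) reject torn cells.
2. **Tissue composition** — a random-forest tile classifier assigns
   adipose/stroma/epithelium labels and reports the relative adipose area.
3. **CLS detection** — colour deconvolution separates the DAB chromogen on
   CD68 immunohistochemistry; an adipocyte is called a CLS when a
   sufficient angular fraction of its peri-cellular annulus is
   CD68-positive.  Patient-level inflammation is CLS per 10 cm² of adipose
   tissue, dichotomised at ≥ 5.
4. **Matched case-control statistics** — conditional logistic regression
   maximises the within-set likelihood
   `L(β) = Π_sets exp(x_case·β) / Σ_{j∈set} exp(x_j·β)`
   by Newton-Raphson, with Wald 95% CIs from the observed information and
   likelihood-ratio p-values; includes pooled quartile coding,
   menopausal-status proxies from age, the p ≤ 0.1 multivariable entry
   rule with interaction tests, and standard group-comparison tests.
5. **Cumulative incidence** — expected cumulative incidence under
   competing mortality from age-specific rate tables
   (`ΔCI = S·λ/(λ+μ)·(1−e^{−(λ+μ)Δt})`), plus subgroup curves derived
   from group prevalences and odds ratios used as rate ratios, constrained
   so the prevalence-weighted group curves reproduce the marginal curve.
6. **Synthetic data** — ground-truthed adipose images (packed perturbed
   disks with exact polygon areas and chord medians, crescent artifacts,
   sub-30 µm debris), CD68 rim overlays, age-matched nested case-control
   cohorts generated by incidence-density sampling with a known
   conditional estimand, and rate tables.  Every pipeline stage is
   validated against this ground truth.

## Worked example

```python
from adiporisk.synthetic import AdipoImageSpec, CohortSpec, generate_adipose_image, generate_cohort
from adiporisk.morphometry import CalibratedRaster, measure_image, summarize_patient
from adiporisk.stats import conditional_logistic_fit, likelihood_ratio_test

# image -> per-patient size summary
spec = AdipoImageSpec(n_cells=100, seed=3)
raster, truth = generate_adipose_image(spec)
kept, rejected = measure_image(CalibratedRaster(raster, spec.microns_per_pixel))
profile = summarize_patient("demo", kept)
print(f"{profile.n_objects_measured} adipocytes measured ({len(rejected)} rejected by QC)")
print(f"adipocyte diameter p75: {profile.diameter_p75_um:.1f} um")
print(f"adipocyte area p75:     {profile.area_p75_um2:.0f} um2")

# matched cohort -> conditional odds ratios
cohort = generate_cohort(CohortSpec(n_sets=500, seed=11))
fit = conditional_logistic_fit(cohort, ["cox2_high", "area_p75_um2"],
                               scales={"area_p75_um2": 1000.0})
null = conditional_logistic_fit(cohort[cohort.set_id.isin(fit.set_ids)], [])
lrt = likelihood_ratio_test(null, fit)
for t, o, (lo, hi) in zip(fit.terms, fit.or_, fit.wald_ci_95):
    print(f"{t}: OR {o:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print(f"LR test vs null: chi2 = {lrt.statistic:.1f}, df = {lrt.df}, p = {lrt.p_value:.2g}")
```

prints

```
100 adipocytes measured (0 rejected by QC)
adipocyte diameter p75: 76.4 um
adipocyte area p75:     4657 um2
cox2_high: OR 4.92 (95% CI 3.55-6.80)
area_p75_um2: OR 1.14 (95% CI 1.05-1.23)
LR test vs null: chi2 = 136.3, df = 2, p = 2.5e-30
```

The cohort generator's true effects here are OR 3.70 for the binary marker
and OR 1.17 per 10³ µm² for the size covariate; a single 500-set replicate
carries sampling error (the binary OR's log-scale SE is ≈ 0.17), which is
why the printed point estimates scatter around those values.  Averaged over
replicates the estimates are unbiased (see `tests/test_cohorts.py` and the
acceptance suite).

A command-line interface mirrors the stages (`adiporisk simulate-image`,
`simulate-cohort`, `simulate-rates`, `measure`, `train-compartments`,
`compose`, `cls`, `fit`, `incidence`); every subcommand reads/writes plain
TIFF/PNG/CSV/JSON.  See `docs/methods.md` for the models, parameter
defaults and known limitations.

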