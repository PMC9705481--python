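# Methods

This note records the models, conventions and design choices behind
`dwiharm`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The problem

Quantitative diffusion-weighted MRI promises scanner-independent tissue
parameters — above all the apparent diffusion coefficient (ADC) — but in
multicenter studies the measured values drift with vendor fitting
algorithms, b-value protocols, receiver gains, coil shading and phantom
temperature. `dwiharm` implements the analysis side of a traveling
phantom / traveling volunteer harmonization study across seven imaging
sites: central ADC computation, temperature-corrected phantom QA,
test-retest and cross-site reproducibility statistics, and a radiomics
chain whose feature selection explicitly rewards cross-site stability.
Because no volunteer scans can be redistributed, a seeded synthetic
generator reproduces the statistical structure the analysis assumes, and
all guarantees are stated on that synthetic population.

## Signal model and ADC estimation

Per voxel, the simulated diffusion signal is

    S(b) = g · β(x) · S0 · [(1 − f) e^{−b·D} + f e^{−b·D*}]

with site gain `g`, a smooth multiplicative bias field `β(x)` (separable
cosine bump, amplitude 2–8 % by default, the minimal model of
coil-sensitivity shading), baseline signal `S0`, true diffusivity `D`
(μm²/s, so `b·D` uses `D·10⁻⁶` mm²/s), and an optional IVIM-like fast
compartment: perfusion fraction `f ∈ [0, 1)` with pseudo-diffusion
`D* > D`. Rician noise is added per b-value volume with scale
`σ/√(averages_b)`, reflecting the protocol's 1/6/23 signal averages at
b = 100/500/900 s/mm².

The estimator is the standard central fit: ordinary least squares of
`ln S(b)` on `b`; ADC = −slope, reported in μm²/s. Choices worth
stating:

* **Unweighted OLS in log space.** No SNR- or average-based weighting;
  the estimator is the plain textbook fit, so closed-form slope
  expressions serve as oracles.
* **b = 0 omitted by default.** The perfusion compartment decays within
  the first tens of s/mm², so including b = 0 inflates the fitted ADC;
  fitting b ≥ 100 only is the harmonizing choice. The generator can
  mark one site as requiring b = 0 (a scanner-software constraint) to
  reproduce the inline-vs-central discrepancy mechanism.
* **Non-positive signals exclude the voxel** (`valid_mask`), never
  clamped — clamping before the log biases the slope.
* **Negative fitted ADCs are retained** so QA statistics see the raw
  estimator.

## Phantom QA

The phantom is a 200 mm sphere with ADC 1600 μm²/s at 20 °C. Its
temperature dependence is modeled as a linear ratio
`ADC(T) = ADC₂₀·(1 + α(T − 20))` with α = 0.024/°C (water-like) and a
validity range of 15–30 °C; dividing a measurement by the ratio maps it
to 20 °C exactly (a bijection on the range). α is configuration, not a
constant of nature — real phantoms ship with calibration curves.

The automatic ROI is a 60 mm circle on the centroid of the valid-fit
voxels of the central slice: large enough for tight statistics, small
enough to avoid edge/partial-volume voxels of the sphere. Cross-site
dispersion is summarized as mean, sample SD (n − 1), CoV = SD/mean and
maximum deviation = (max − min)/mean · 100. The denominators deserve a
note: published summaries rarely state whether a ± value is a cross-site
or a within-ROI SD, so the report carries both; and maximum deviation is
normalized by the cross-site mean as the most natural reading of a
"highest minus lowest" percentage.

## Reproducibility statistics

ROI analysis uses 11 circular 2D masks of 250 mm² (radius ≈ 8.92 mm) at
fixed anatomical positions in 5 organ classes (left/right kidney; liver
segments 4, 7, 8; two spleen positions; left/right quadratus lumborum;
lumbar vertebrae 1–2). Rasterization takes the `round(250/pixel-area)`
pixels nearest the circle center — a disc whose area is within half a
pixel of nominal for any in-plane spacing up to 2.6 mm.

* **Bland-Altman**: per-pair relative difference
  `(m₂ − m₁)/((m₁ + m₂)/2)·100` (pair-mean denominator, the standard
  percent-scale convention; the first-measurement denominator is carried
  alongside since published plots often leave this implicit), summary
  mean, SD, and limits of agreement mean ± 1.96 SD.
* **Traveling comparison**: per-ROI deviation relative to the reference
  site's mean; the reference row is identically zero.
* **Wilcoxon signed-rank**: zeros dropped (Wilcoxon's rule), exact null
  for n ≤ 25 without ties, normal approximation otherwise; significance
  at the Bonferroni-adjusted p < 0.007. The exact branch is verified
  against full 2ⁿ sign enumeration in the tests.
* No outlier rejection anywhere.

## Radiomics chain

1. **Resampling** to 1 × 1 × 1 mm³ (trilinear images / nearest-neighbor
   masks, nearest-neighbor extrapolation at the boundary so edge voxels
   are not zero-filled).
2. **Histogram matching** (T2w only) to the reference site: 10 quantile
   match points over a 128-level histogram, foreground thresholded at
   the volume mean — ITK's landmark-matching filter, i.e. the same
   algorithm behind 3D Slicer's module. ADC skips matching by default:
   it is already quantitative, and matching would erase the scale the
   pipeline works to harmonize (configurable override).
3. **Features**: 26 per ROI — 18 first-order statistics and 8 GLCM
   texture features (contrast, dissimilarity, homogeneity, angular
   second moment, joint entropy, correlation, cluster shade, cluster
   prominence). Conventions: population (n) variance; kurtosis as
   m₄/m₂² (normal → 3); skewness 0 and correlation 0 for zero-variance
   ROIs; entropy/uniformity on a fixed-bin-count (32) histogram; GLCM on
   the same 32-level discretization, distance-1 co-occurrences
   accumulated symmetrically and feature values averaged over the 13
   unique 3D directions. A fixed bin *count* (not width) keeps bins
   aligned across sites after histogram matching. The 3D co-occurrence
   accumulation is implemented here directly (array-shift counting);
   external extractors can substitute any table with the same key
   columns.
4. **Stability filter**: for each feature, each site contributes the
   vector of values over the 11 anatomical positions; the score is the
   mean |Pearson r| over all 21 site pairs, and features with score
   ≥ 0.75 survive (the threshold value itself survives). This statistic
   is invariant to per-site affine rescaling — precisely why it
   tolerates vendor gain differences while killing site-driven
   features. Zero-variance vectors contribute r = 0 with a log entry.
   With a single traveling volunteer this per-position-vector reading is
   the only way to obtain a per-feature correlation, and it is recorded
   prominently because "correlation across sites" is genuinely
   ambiguous.
5. **ANOVA-F selection**: one-way F of each surviving feature against
   the 5 organ classes; top N = 15, ties broken lexicographically. The
   two stages are also exposed as sklearn-style transformers
   (`StabilityFilter`, `AnovaFSelector`) that compose in a `Pipeline`.

## Classification and distances

The classifier is a random forest with 1000 trees and maximum depth 10,
scikit-learn defaults otherwise. Leave-one-site-out cross-validation
repeats 10 seeded runs; accuracies are reported per held-out site as
mean ± SD **over runs** (with a shared-seed mode in which that SD is
numerically zero, down to the familiar ~10⁻¹⁶ float residue). The
test-retest experiment trains on all first-acquisition rows and
predicts the retest rows, 5 seeded runs.

ROC curves are one-vs-rest per organ, computed per (run, held-out site)
group, interpolated onto a fixed 101-point FPR grid for macro-averaging;
each curve's AUC is integrated from the raw (uninterpolated) curve.
Groups with a single class are skipped with a log entry.

The first Wasserstein distance between ROI intensity samples is computed
exactly from the empirical distributions (scipy's quantile-function
integral; pre-binned histograms are accepted as weighted samples). The
matrix is min-max normalized over off-diagonal entries to [0, 1] with
the diagonal forced to zero. tSNE (seeded, perplexity auto-shrunk to
(n−1)/3 when rows are few) is visualization only and carries no
acceptance weight.

## What the generator emulates — and what it does not

Emulated: per-site gain (0.8–1.25), Rician noise (σ 10–30 before
averaging), smooth bias fields, one b0-requiring site per 7-site
manifest, one reference site, phantom bath temperatures 18–24 °C with
the matching physical ADC shift, per-organ ADC/T2w means with voxelwise
heterogeneity (liver 965 μm²/s and gray value 480 with ~22 % spread,
anchored to in-vivo liver statistics; other organs are stipulated at
plausible values), unspecific body tissue between organs so global
histograms are tissue- rather than air-dominated, and ≤ 3 mm ROI
re-placement jitter between test and retest.

Not emulated: real anatomy (organs are ellipsoids), k-space/EPI
artifacts, motion, field-strength-dependent relaxation, vendor
reconstruction pipelines, inter-reader ROI variability. Consequently,
passing tests demonstrate that the *analysis* behaves correctly and that
its mechanisms (perfusion bias, gain invariance, stability filtering)
act as designed — not that real seven-site accuracies or deviation
envelopes are reproduced. Synthetic organs are cleaner than anatomy, so
classification accuracies on synthetic data sit near the separable
ceiling rather than at in-vivo levels.

## Problem sizes and numerical choices

Default grids are 96 × 96 × 14 voxels at 2.6 × 2.6 × 5 mm for volunteers
and 64 × 64 × 56 at 4 mm for the phantom — small enough that the whole
seven-site study (all three scenarios, all stages) runs in minutes on
one CPU, while every ROI keeps ≥ 30 in-plane voxels. Sub-seeds for
every stochastic stage derive from one study seed via
`numpy.random.SeedSequence`, making all outputs bit-reproducible.
Degenerate inputs fail loudly: constant volumes (histogram matching),
empty valid masks (phantom QA), unmatched pair keys, training folds
missing an organ class, temperatures outside calibration range.

## Known limitations

* The calibration coefficient α and all non-liver tissue parameters are
  stipulations; swap in phantom- or cohort-specific values via
  configuration for real data.
* The built-in extractor computes 26 features, not the thousand-plus of
  a full radiomics toolkit; the selection stages are extractor-agnostic
  by design.
* The stability score assumes all sites share the same 11 ROI
  positions; missing ROIs must be handled upstream.
* Inline (scanner-side) ADC maps are emulated only through the
  b-value-set mechanism, not through vendor-specific fitting quirks.
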