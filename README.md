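# dwiharm

Multicenter harmonization analysis for quantitative abdominal MRI:
central ADC mapping from diffusion-weighted imaging, temperature-corrected
phantom QA, test-retest / traveling-volunteer reproducibility statistics,
and a radiomics chain with cross-site stability feature selection and
leave-one-site-out classification — plus a seeded synthetic multi-site
generator so the whole pipeline is testable without any scan data.

## Who this is for

Imaging scientists running (or simulating) traveling-phantom /
traveling-volunteer studies across several MRI sites who need a common,
vendor-independent analysis: the same ADC fit everywhere, phantom QA
normalized to a common temperature, ROI-level agreement statistics, and
radiomic features that survive scanner changes.

## The core model

The apparent diffusion coefficient is estimated per voxel from the
monoexponential decay model

```
S(b) = S0 · exp(−b · ADC)
```

by ordinary least squares of `ln S(b)` on the b-values (100, 500,
900 s/mm² by default); ADC = −slope, reported in μm²/s. b = 0 is omitted
by default because an IVIM-like perfusion compartment
(`S(b) ∝ (1−f)e^{−bD} + f e^{−bD*}`, `D* ≫ D`) inflates b0-inclusive
fits — the central mechanism behind inline-vs-central ADC discrepancies.

Phantom measurements at temperature T are mapped to 20 °C via a linear
calibration ratio `ADC(T) = ADC₂₀(1 + α(T − 20))`, and cross-site
dispersion is summarized by CoV = SD/mean and the max–min deviation.
Radiomic features (18 first-order + 8 GLCM) are selected in two stages:
a cross-site stability filter (mean |Pearson r| of per-site feature
vectors over the 11 anatomical ROI positions, threshold 0.75) followed
by one-way ANOVA-F ranking against the 5 organ classes (top 15). Organ
prediction uses a 1000-tree random forest (depth 10) in 10 runs of
leave-one-site-out cross-validation; distributional similarity of ROIs
is measured by the first Wasserstein distance between intensity
histograms. See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
from dwiharm.synthdata import generate_site_manifest, generate_study
from dwiharm.phantomqa import phantom_report, cov_from_summary

# CoV from a printed cross-site summary (mean ± SD)
print(f"{cov_from_summary(1617, 22):.4f}  {cov_from_summary(1624, 16):.4f}")

# 7-site phantom scenario: simulate, fit ADC, auto-ROI, temperature-correct
manifest = generate_site_manifest(7, seed=1)
study = generate_study(manifest, "phantom", seed=2)
table, stats = phantom_report(study)
print(table[["site", "temperature_c", "central_mean_raw", "central_mean_20c"]]
      .round(1).to_string(index=False))
raw, corr = stats["central_raw"], stats["central_corrected"]
print(f"CoV raw {raw.cov:.4f} -> corrected {corr.cov:.4f}; "
      f"max deviation {corr.max_deviation_pct:.2f}%")
```

prints

```
0.0136  0.0099
site  temperature_c  central_mean_raw  central_mean_20c
   A           22.8            1706.5            1598.3
   B           20.0            1597.9            1599.4
   C           18.7            1551.1            1601.3
   D           18.3            1536.9            1603.0
   E           23.4            1730.8            1600.4
   F           23.0            1715.7            1599.9
   G           21.9            1671.3            1597.6
CoV raw 0.0494 -> corrected 0.0011; max deviation 0.33%
```

The first line is the coefficient of variation implied by two printed
phantom summaries (1617 ± 22 and 1624 ± 16 μm²/s). The table shows each
site's phantom ADC mean before and after normalization to 20 °C: the
bath temperatures (18–24 °C) drive almost all of the apparent
cross-site spread, and the correction collapses the CoV from ~5 % to
~0.1 %, with every corrected mean within a few μm²/s of the 1600 μm²/s
ground truth.

The same workflows are available from the shell:

```
dwiharm synth --scenario test-retest --sites 7 --seed 1 --out ds/
dwiharm phantomqa --dataset ds/ --out report.json
dwiharm repro --dataset ds/ --mode test-retest --modality adc --out out/
dwiharm radiomics extract --dataset ds/ --modality adc --out features.csv
dwiharm classify loso --features features.csv --out out/
```

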