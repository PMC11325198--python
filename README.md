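# emsims

Correlative EM–nanoSIMS analysis of protein turnover, with a synthetic
acquisition test bench.

## The problem

Metabolic labeling with a fully ^15N diet marks newly synthesized proteins,
and nanoscale secondary ion mass spectrometry (nanoSIMS) images the label at
~30 nm pixels as two simultaneously acquired ion-count channels, ^12C^14N⁻
("old" nitrogen) and ^12C^15N⁻ ("new" nitrogen). Correlating the SIMS scan
with a transmission EM image of the same ultrathin section lets one ask, per
identified structure — presynapse, postsynapse, active zone, PSD, myelin,
axon, neurite, mitochondrion — how metabolically old it is, and whether its
morphology (section area, vesicle number, PSD length, myelin thickness,
nascent zones) predicts its turnover.

`emsims` implements that pipeline for anyone doing correlative isotope
imaging of tissue:

* **Quantification** — per-pixel ratio maps `R = C15/C14` with validity
  masking; per-ROI *ratio of sums* `R_ROI = ΣC15 / ΣC14` (the Poisson
  maximum-likelihood estimate of a common ratio) with delta-method standard
  errors; HSI-style display images scaled by 10⁴ and clamped to [37, 2500],
  where 37 is the natural ^15N abundance of 0.37%.
* **Registration** — a 6-parameter affine EM→SIMS map fitted by least
  squares from landmark pairs, replacing manual overlay.
* **Morphometry** — shoelace areas, longest axis (max Feret diameter of the
  drawing), vesicle counts inside boutons, myelin thickness as
  equivalent-radius difference, mitochondrion location by centroid
  containment.
* **Cohort statistics** — Mann–Whitney contrasts of each structure against
  the per-image whole-area baseline with Bonferroni correction; young/aged
  contrasts after whole-organ normalization (global shifts cancel);
  morphometry of top-k vs bottom-k turnover subsets by Wilcoxon rank-sum
  (exact permutation enumeration at small n); nascent-zone percentages with
  a paired signed-rank test across region × age strata; paired pre/post OLS
  regressions with R² and slope-t p-values.
* **Synthetic scenes** — since no public paired dataset exists, a generator
  builds labeled fields of all eight structure classes with known per-object
  ratios (lognormal dispersion, size–enrichment coupling, correlated
  pre/post pairs, enrichment-coupled nascent zones) and simulates the
  acquisition as independent Poisson channels
  `C14 ~ Poisson(λ/(1+r))`, `C15 ~ Poisson(λr/(1+r))`.

## Worked example

```python
import numpy as np
from emsims import (SceneSpec, AcquisitionParams, build_scene,
                    simulate_acquisition, ratio_map, display_image,
                    whole_area_ratio, roi_ratio)
from emsims.geometry import polygon_mask

spec = SceneSpec(seed=1)        # 15 um field, 512 px, 8 structure classes
truth = build_scene(spec)
pair = simulate_acquisition(truth, AcquisitionParams(seed=2))

whole = whole_area_ratio(pair)
print(f"whole-area 15N/14N ratio: {whole.ratio:.5f} (SE {whole.se:.2e})")

for cls in ("myelin", "presynapse", "PSD"):
    objs = [o for o in truth.objects if o.structure == cls]
    s15 = s14 = 0
    for o in objs:
        mask = polygon_mask(o.polygon, pair.shape)
        if o.inner_contour is not None:
            mask &= ~polygon_mask(o.inner_contour, pair.shape)
        r = roi_ratio(pair, mask)
        s15 += r.sum15; s14 += r.sum14
    true_mean = np.mean([o.true_ratio for o in objs])
    print(f"{cls:11s} n={len(objs)}  measured {s15/s14:.5f}   true mean {true_mean:.5f}")

disp = display_image(ratio_map(pair))
print(f"display range: [{disp.values.min():.0f}, {disp.values.max():.0f}]")
```

prints

```
whole-area 15N/14N ratio: 0.00405 (SE 4.41e-06)
myelin      n=2  measured 0.00394   true mean 0.00389
presynapse  n=8  measured 0.01276   true mean 0.01284
PSD         n=8  measured 0.01489   true mean 0.01451
display range: [37, 379]
```

The whole-area ratio sits just above the natural 0.0037 baseline (the field
is mostly unlabeled background); myelin is the least and the PSD the most
enriched structure, and each measured ratio-of-sums tracks the generating
per-object truth to within counting noise. On the display scale the
background renders at the lower clamp 37.

The same analysis runs from the shell on a simulated cohort of three brain
regions × two ages:

```bash
emsims full --seed 1 --out results/run
```

which writes `turnover_table.csv` (one row per ROI), `morphometry.csv`,
`contrasts_whole.csv`, `age_contrasts.csv`, `extreme_morphology.csv`,
`nascent_contrast.csv`, `paired_regressions.csv`, display PNG/TIFFs and a
reproducibility manifest. `emsims simulate` writes just the fixture file set
(count TIFFs, label TIFF, GeoJSON annotations, landmark CSV, truth CSV);
`emsims analyze --config cfg.yaml` consumes such fixtures, including ones
you provide yourself.

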