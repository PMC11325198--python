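# Methods

## Measurement model

A nanoSIMS acquisition of an ultrathin section yields two co-registered
ion-count images, ^12C^14N⁻ and ^12C^15N⁻ (written C14, C15). Counting is
shot-noise limited, so the package models each pixel of a structure with
total CN⁻ yield λ (counts/pixel) and true isotope ratio r as independent
Poisson draws

    C14 ~ Poisson(λ / (1+r)),    C15 ~ Poisson(λ·r / (1+r)).

This parameterization keeps the total expected yield at λ regardless of r
and makes the expected count ratio exactly r. Detector dead time,
quasi-simultaneous-arrival effects, isobaric interference and multi-plane
accumulation are out of scope (single-plane acquisition is assumed).

### ROI statistic

The per-ROI turnover readout is the **ratio of sums**, R = ΣC15 / ΣC14 over
the ROI's pixels. For Poisson channels with a common r this is the
maximum-likelihood estimate and weights pixels by information content; the
per-pixel-ratio mean is available as a flagged `mean_of_ratios` option for
sensitivity analysis only. Pixels with C14 = 0 have no defined per-pixel
ratio and are flagged invalid, but their C15 counts still enter the ROI
numerator (counts are physical); an ROI is rejected only when ΣC14 = 0. The
delta-method standard error is SE(R) = R·√(1/ΣC15 + 1/ΣC14) with the
observed sums as plug-in estimates; when ΣC15 = 0 a one-count floor is used
in the numerator term.

### Display convention

Ratio maps are rendered on a per-10⁴ scale clamped to [37, 2500]: the lower
clamp corresponds to the natural ^15N abundance of 0.37% (0.0037), the upper
clamp saturates ratios ≥ 0.25. The scale factor 10⁴ is inferred from that
0.37% ↔ 37 correspondence and lives in `DisplayConfig`, not in code paths.
Invalid pixels render at the lower clamp and are reported as a count.

## Registration

EM and SIMS frames are related by a 6-parameter affine map fitted by linear
least squares from landmark point pairs, minimizing squared SIMS-frame
residuals. An affine rather than similarity model is the default because
scan distortions include anisotropic stretch; a similarity (Procrustes) fit
is available for comparison. Three non-collinear pairs interpolate exactly;
collinear or insufficient landmarks raise a dedicated error. Landmarks are
user- or truth-supplied; there is no automatic feature matching (the
corresponding manual step is interactive overlay).

## Morphometry

All measures are computed on EM-frame polygons (pixel units) and converted
with the pixel pitch. Choices made where the measurement rule was open:

* **Longest axis** = maximum pairwise distance over outline vertices (max
  Feret diameter of the drawing). Computed via the convex hull, which is
  exact for this statistic.
* **Myelin thickness** = equivalent-radius difference
  √(A_outer/π) − √(A_inner/π), exact for concentric circles and robust to
  hand-drawn contour noise; per-normal distance averaging was rejected as
  unstable on irregular hand drawings.
* **Mitochondrion location**: presynaptic iff its centroid lies inside a
  presynapse polygon. A ≥50%-overlap rule agrees except for boundary
  straddlers (test-verified); disagreements are logged, not failed.
* **Vesicle counting** is boundary-inclusive point-in-polygon; **docked**
  vesicles are those within 50 nm of the active-zone outline — a convention
  of this package (one vesicle diameter), flagged as unanchored.
* **Nascent-zone status** is an annotation input, not an image-derived
  detection.

Pixel convention everywhere: 0-based indices, the center of pixel
(row i, col j) at (x=j, y=i), rows increasing downward; a pixel belongs to a
polygon when its center does (boundary inclusive).

## Synthetic scenes

No public paired EM-annotation/ion-count dataset exists, so validation runs
on generated scenes. The default field is 15 µm square at 512 px (29.3 nm
pixels, within the instrument's usual 20–43 nm; 256/512/1024 formats are
standard, others warn). A field holds myelin annuli wrapped around axon
cores, standalone axons, elongated neurites, elliptical mitochondria, and
apposed pre/postsynapse blob pairs carrying an active-zone band on the
presynaptic face, a PSD band on the postsynaptic face, and uniformly placed
vesicle points (75/µm² of bouton profile). Placement is rejection sampling
without overlap (largest structures first); sub-compartments overlap their
parents by design, with parentage recorded.

### Enrichment model

Each object of class c has true ratio

    r = μ_c · exp(β·z + σ·g − (β² + σ²)/2)

with z the standardized log-size deviate (radii are lognormal, log-SD 0.25),
g ~ N(0,1), σ = √ln(1+cv²) from the enrichment coefficient of variation
(default cv = 0.3), and β the size–enrichment coupling (default −0.3:
larger structures are metabolically older, giving the detection stages a
positive control; β = 0 is the null fixture). E[r] = μ_c exactly. Default
class means after 21 d of labeling: myelin 0.006 < axon 0.009 < neurite
0.010 < mitochondrion 0.011 < presynapse 0.014 < postsynapse 0.015 <
active zone = PSD 0.018; background is the natural 0.0037. Active zones and
PSDs inherit their parent's ratio scaled by μ_child/μ_parent with halved
extra dispersion, so sub-compartment enrichment is correlated with — and on
average boosted above — its parent.

`pair_correlation_rho` (default 0.7) is defined as the **Pearson correlation
of paired pre/post true ratios**. Both the size and dispersion deviates of a
pair are drawn from a Gaussian copula whose latent correlation is solved
from the lognormal moment identity ρ_g = ln(1 + ρ(e^{s²}−1))/s², s² = β²+σ²,
so the target is met for any |ρ| ≤ 1 at the default dispersions. Nascent
flags are Bernoulli with P = logistic(slope · standardized log-ratio) over
the scene's PSDs (default slope 2).

Myelin sheath width shares the size deviate (mean 150 nm), so thickness
couples to enrichment through β, mirroring the outer-size coupling.

### Object-level sampling path

Summed Poisson counts over a uniform-ratio ROI are distribution-identical to
one Poisson draw of the summed rates, so `sample_cohort` draws per-object
count sums directly (Λ = λ_c · area) without rasterizing. This makes
hundreds of cohort repeats cheap while exercising exactly the same
enrichment model; the imaging path's equivalence is covered by full-scene
ratio-recovery tests. Sampled cohorts are treated as pooled over as many
scanned fields as needed for annotated objects to cover 5% of the total
area — hand annotation covers a small fraction of each field — with the
remainder contributing background counts to the whole-area sums.

### What the generator does not emulate

Real EM contrast, segmentation error, vesicle clustering (placement is
uniform — not a claim about real boutons), drift, topography/charging
artifacts, within-object enrichment gradients, or animal-level nesting.
Passing tests therefore demonstrate correctness of the measurement and
statistical machinery under the stated stochastic model, not biological
validity on real tissue.

## Cohort statistics

* **Structure vs whole area**: two-sided Mann–Whitney of each class's
  per-object ratios against the per-image whole-area ratios, Bonferroni
  factor = number of classes actually tested (reported alongside raw p;
  corrected p = min(1, m·p)).
* **Rank-sum p-values**: exhaustive permutation enumeration for pooled
  n ≤ 16 (exact even under ties); the exact no-tie distribution for group
  sizes ≤ 25 without ties; tie-corrected normal approximation with
  continuity correction otherwise. Full enumeration with ties beyond ~16
  pooled observations is combinatorially infeasible, hence the hybrid.
* **Young vs aged**: all ratios are divided by their cohort stratum's
  whole-organ average — the ratio of summed counts over all analyzed images
  of that region + age when per-image sums are available, else the mean of
  per-image whole-area ratios — then per-class, per-region aged/young
  quotients of the normalized means are tested against 1 with a two-sided
  one-sample t-test across regions, Bonferroni over the classes tested. A
  global multiplicative shift of one cohort cancels exactly. Note that a
  *class-specific* shift is absorbed into the whole-organ average in
  proportion to that class's share of total counts; with annotated
  structures at a few percent of the imaged area the absorption is < 1%.
* **Extreme subsets**: top-k and bottom-k objects by ratio (rank-based, not
  threshold-based; k defaults to 18, in the 15–20 range used per
  condition), ties broken by object id for determinism. Morphometry is
  compared between the groups by the two-sample Wilcoxon rank-sum test,
  one- or two-sided as requested.
* **Nascent zones**: percentage of flagged PSDs in the high vs low group per
  region × age stratum, compared by a paired Wilcoxon signed-rank across
  strata (zsplit zero handling); an all-zero difference vector is reported
  as degenerate with p = 1.
* **Paired regressions**: OLS of the y-class ratio on the x-class ratio over
  shared pair ids; R² is the squared Pearson correlation and p the slope
  t-test. Constant y yields a flagged degenerate result (R² = 0, p = 1);
  constant x raises.

## Pipeline

One global seed is split into named CRC-keyed substreams per stage and per
field, so any stage can be re-run in isolation and identical configuration +
seed yields byte-identical result tables. The simulated cohort spans three
regions × two ages; aged enrichments are the young ones scaled by 0.81 (the
~19% global slowdown expected from proteome-wide aging data) with an extra
presynaptic factor 0.95 as a planted, recoverable age effect. The natural
background does *not* scale with age (unlabeled material is age-blind),
which at the default fixture's background-dominated whole-image ratio makes
the pipeline's own age normalization only partially cancel the global shift
— a faithful property of resin-dominated synthetic fields, noted to avoid
misreading the default run's `age_contrasts.csv`.

## Verification sizes

The acceptance computations use: one default 512-px scene (λ = 800/px) for
per-class ratio recovery; 4,000 objects per synaptic class per region for
the normalization checks (sampling SD of the class mean-over-regions
≈ 0.006, well inside the ±0.02 criterion); 200 seeded repeats of 60
presynapses with k = 20 for null calibration and power; 200 pre/post pairs
at ρ = 0.7 for correlation recovery; 10⁶ Monte-Carlo samples for the area
oracle.

## Known limitations

2-D section profiles only (no 3-D volumes); no intensity-based or deformable
registration; no mixed-effects modeling of animal nesting (objects are
pooled); Bonferroni is the only built-in multiplicity correction; mitochondria
are never placed inside presynapses by the generator, so the pipeline's
`in_presynapse` flag is exercised geometrically rather than by planted
effects.
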