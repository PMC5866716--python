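# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Synthetic landscapes

The generator stands in for a real monitored site. Each of K habitat
classes gets an independent standard-normal random field smoothed with a
Gaussian kernel of width `patch_scale` pixels (default 6; at 30 m pixels
that makes ~180 m patches, the scale of dune slacks and marsh fragments).
Every pixel takes the class whose bias-shifted field is largest; the
per-class biases are calibrated by a fixed-point iteration (≤ 200 steps,
stopping when every class share is within 0.2 points of target) so that
realized class proportions track `target_proportions`. A class with a zero
target — burn scars before any fire — receives a −∞ bias and therefore no
pixels. The whole construction is a pure function of the configuration and
seed.

Two-date scenarios reuse the first date's fields with persistence weight
0.9 plus fresh innovation (variance-preserving AR(1) mixing), so most of
the landscape persists and change concentrates along patch edges, as in a
real bi-temporal comparison. The default per-date class shares are shaped
on a coastal-wetland mosaic: the second date trades grassland and salt
marsh for forest, reed bed and burned area.

Reflectance is `class mean(season, band) + N(0, noise_sd)` clipped to
[0, 1]. The default eight-class signature set spans 6 reflective bands ×
2 seasons with plausible values (bright sand, dark water with negative
NDVI, strong reed-bed phenology between spring and autumn) and a default
`noise_sd` of 0.02 reflectance units; every class pair is separated by at
least 0.1 (five noise SDs) in some season/band. What the generator does
*not* emulate: mixed pixels and ecotone gradients, sensor PSF and
atmospheric effects, tides, intra-class spectral heterogeneity, and
inter-annual calibration drift. Passing tests therefore demonstrate the
correctness of the machinery and its behaviour under the stated noise
model — not that any particular accuracy would be reached on real imagery,
where class overlap is far larger.

Reference areas are axis-aligned rectangles of `min_area`–`max_area`
pixels (default 2–12), placed by seeded rejection sampling subject to
homogeneity (all covered pixels share the polygon's class) and
non-overlap; for heavily fragmented classes the sampler falls back to
single-pixel rectangles before raising. Roles (training/validation) are
fixed per polygon and shuffled within a class so neither role is biased
toward easier placements. Polygon sizes are configurable because real
digitized-area sizes are study-specific; counts per class can be given as
totals plus a role fraction, or as explicit (training, validation) pairs
to mirror a published sampling design exactly.

## Features

Per year, the classifier input is every reflective band of both seasonal
acquisitions plus NDVI and NDWI per season. NDWI is the green/NIR
(open-water) variant. Zero-denominator index pixels become nodata, and the
stack's nodata mask is the union of all layer masks. Calibration units are
treated as opaque: the learners see whatever radiometric scale the input
is in, and the synthetic path generates reflectance directly, bypassing
`dn_to_radiance`.

## Classifiers

The ten roster ids map to scikit-learn estimators, each wrapped with a
feature scaler where the family needs one. Two families have no exact
scikit-learn counterpart and alias to the closest available relative —
adaptive mixture discriminant analysis → regularized QDA and mixture
discriminant analysis → LDA — recorded in `ROSTER_NOTES` and logged at
training time. The PLS classifier is the standard PLS-DA construction
(PLS regression on one-hot indicators, argmax prediction); the averaged
neural network is the soft-vote mean of five identically configured MLPs
with different initialisation seeds. Hyperparameters are documented
defaults, overridable per algorithm via the pipeline YAML; no tuning or
cross-validation search is performed, and class imbalance is left
uncorrected. All stochastic learners receive an explicit seed, so training
is deterministic given (samples, spec).

## Accuracy assessment and screening

Confusion matrices are oriented rows = predicted, columns = reference, and
the accuracy unit is the validation pixel. Producer's accuracy is
reference-conditioned (1 − omission error) and user's accuracy
prediction-conditioned (1 − commission error) — the conventional
correspondence, which this package follows even though parts of the
applied literature occasionally invert the phrasing. Undefined quantities
(zero marginals; κ when chance agreement equals 1) are NaN, never 0.

McNemar's test uses the discordant counts with the continuity correction
on by default (configurable off); `b + c = 0` is defined as statistic 0,
p = 1. The correction term is not clamped at zero, matching the textbook
formula and statsmodels. No multiple-testing adjustment is applied across
the 45 pairwise tests by default (Bonferroni and Holm are available),
matching common practice in map-comparison studies. Screening excludes
algorithm i iff some j has p(i,j) < α and strictly higher overall
accuracy; consequently the top-accuracy algorithm can never be excluded.

## Ensembles

Votes are per-pixel label counts (simple) or accuracy-weighted counts.
Tie-break, chosen because the voting literature rarely specifies one:
among tied classes, prefer the class supported by the member with the
highest tie-break weight (overall accuracy); final fallback is the lowest
class id. The rule is deterministic and member-order independent — members
are internally processed in id order so even floating-point summation
order cannot depend on input order — and tie-decided pixels are counted
and returned as a mask. A nodata member pixel abstains; the fused pixel is
nodata only when all members abstain. Weighted voting is invariant to a
common rescaling of the weights, so overall accuracies are used
unnormalized.

## Change analysis

Transition matrices cross-tabulate pixels valid at both dates on the
union of both legends, in hectares (pixel area defaults to the grid's,
0.09 ha for 30 m pixels). Percent change per class is computed from the
matrix marginals rather than from independently counted maps, so nodata
exclusion is identical at both dates; a class absent at the first date has
undefined (NaN) change. Negative means loss; the tidy summary also
reports magnitude with a loss/gain tag.

The shipped `data/table3_transitions.csv` holds a published pair of
ensemble transition matrices (2003 → 2016, 984 ha coastal wetland)
verbatim; every cell is an integer multiple of 0.09 ha, confirming the
pixel-area convention. One internal inconsistency in that source is known:
the grasslands decrease recomputed from the weighted-vote block (−28.3 %)
exceeds the upper bound of the summary range printed alongside it
(26.5 %); the package reports what the marginals imply and leaves the
discrepancy documented here.

## Pipeline and numerical conventions

One global seed drives everything; each stage derives its own seed as
`(seed · 1000003 + crc32(stage name)) mod 2^31`, giving stage-level
reproducibility without bookkeeping. Reruns with one configuration are
file-for-file identical; the manifest lists every artifact with a
configuration digest. Raster coverage uses 0-based row/col indexing and
pixel-center containment, half-open on the max edges, so adjacent
polygons never double-count a pixel. Rasters are written as GeoTIFF with
ModelPixelScale/ModelTiepoint tags plus a JSON sidecar for legends;
reference areas as GeoJSON.

Default experiment sizes — 120×120 pixels, 30 polygons per present class,
validation ≈ 550 pixels per date — were chosen as the smallest scenario
that keeps every class's patch structure and validation margins
statistically meaningful while remaining quick on a single CPU.

## Known limitations

* Accuracy on the synthetic scenes is near-ceiling by design (separable
  signatures); it characterises machinery, not expected real-world skill.
* No area-adjusted (stratified-estimator) accuracy or κ variance.
* No atmospheric or cross-sensor harmonization; calibration is a linear
  gain/offset only.
* Ensembles are hard-vote only; no probabilistic fusion or stacking.
* The mixture-discriminant roster entries are aliases (see above), so
  their results characterise the aliased estimators.
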