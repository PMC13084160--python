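# Methods

## Scope and model

`ncfish` quantifies compartment-resolved single-molecule FISH and
immunofluorescence images of cultured neurons. The object model is:

- an **ImageScene** — co-registered channel grids (marker, nuclear stain,
  mRNA, ribosome, mitochondria, …) with a physical pixel size;
- a **cell geometry** — a user-traced soma polygon and per-neurite
  centerline polylines, expanded into corridor masks;
- **objects** — subpixel point detections (mRNA spots) and thresholded
  particles (ribosomal clusters, mitochondria, PLA puncta);
- **readouts** — per-compartment counts, areas, densities, overlap
  fractions, intensity normalizations, and the statistics attached to
  them.

Coordinates are 0-based (row, col) pixel indices with pixel centers at
integers; physical lengths are pixel lengths × `pixel_size_um`. The
default pixel size is 0.05 µm/px, a realistic lateral sampling for a
63×/1.63 NA super-resolution acquisition; other values, including the
0.01 µm/px sometimes found in microscope metadata, are accepted via
configuration.

## Preprocessing

Z-stacks are reduced by maximum-intensity projection. The colocalization
chain blurs with a Gaussian (σ = 1 px, reflective boundaries — reflection
preserves intensity mass at the edges of straightened neurite crops) and
offers contrast-limited adaptive histogram equalization with block
127 px and max slope 6; the CLAHE clip limit is `max_slope` × the uniform
bin height, implemented via scikit-image (`clip_limit = max_slope /
nbins`). Bit-parity with any particular desktop CLAHE is not promised;
the contract is the clip-limited equalization plus the invariance tests
(constant image fixed, per-block rank preservation, bounded range).

Thresholding is Otsu by default, with a manual override; the realized
threshold is logged. One consequence discovered while validating on
synthetic data: Otsu requires a bimodal histogram, which CLAHE
deliberately destroys on sparse-signal images (it stretches background
noise to full range). The pipeline therefore thresholds the *blurred*
image by default and reserves CLAHE for manual-threshold workflows and
display (`use_clahe` in `PipelineConfig`).

## Spot detection

Spots are detected on the min–max-normalized image with a difference of
Gaussians, `G(σ) − G(1.6σ)`, σ default 1.4975 px; every 3×3 local maximum
with response ≥ the threshold becomes a candidate, refined to subpixel
position by an axis-wise quadratic fit (offsets clipped to ±0.5 px) and
deduplicated within `min_separation_px` (2 px) keeping the stronger
response. The printed defaults of the original analysis (DoG threshold
0.01413707, anisotropy 1.4176076650619507 for z-scaling in 3D) are kept.

The robust-fitting refinement of the original detector (multiconsensus
RANSAC) is replaced by the quadratic fit: the quantification contract
here is counts and positions scored against planted truth, not
bit-parity with another implementation. Because a fixed response
threshold is only meaningful for one dataset's intensity scale — the
original analysis tuned it on a representative image before applying it
everywhere — the detector offers `threshold_mode="auto"`: threshold =
median + 8 × MAD-σ of the DoG response, floored at the printed value.
This reproduces the tune-then-apply procedure deterministically. On
synthetic scenes with spot amplitude 10× the noise SD, auto mode yields
F1 ≥ 0.98 per scene; the fixed printed threshold sits ≈2σ above the DoG
noise floor there and drowns in false maxima, which is why pipelines
default to auto.

## Masks, straightening, compartments

The soma mask is the thresholded marker channel restricted to the traced
soma polygon (the thresholded nuclear stain, when given, is unioned into
the marker support); each neurite mask is the thresholded marker
restricted to the centerline corridor (width default 75 px, the midpoint
of the published 50–100 px range; the corridor alone is available via
`corridor_only`). Pixels at the soma–neurite junction belong to the
neurite, making the masks disjoint. Straightening resamples the image
bilinearly along the centerline: column *j* is arc length *j*, rows span
the corridor normal; an axis-aligned path therefore reproduces its crop
exactly, and corridor intensity is preserved within the bilinear
resampling error (≈2% on smooth images).

Compartments are arc-length intervals: proximal = first 20 µm from the
soma, distal = last 20 µm, middle = the rest. Neurites shorter than
40 µm raise rather than silently collapsing to fewer compartments — the
caller decides. Objects are assigned by centroid containment, with arc
position taken from the nearest centerline point; compartment areas are
computed by the same nearest-centerline rule applied to mask pixels, so
density = count/area uses one consistent geometry.

## Colocalization

A reference object counts as colocalized when the fraction of *its own*
pixel support covered by some target object reaches the threshold
(default ≥50%). The denominator is deliberately the reference channel
(the mRNA in mRNA-vs-ribosome questions); both directions can be
computed by swapping arguments. Point detections get a disk footprint of
radius ⌈2σ_DoG⌉ px, since a point has no area; the radius is
configurable because the true spot footprint is an imaging property, not
a detection one. Tripartite colocalization requires the reference object
to meet the threshold against both other channels independently.
Mander's coefficients are computed on preprocessed images within the
analysis mask; the thresholds used enter the report. Line scans average
bilinear samples across the corridor normal at each arc step.

## Synthetic scenes

The generator renders what the assays measure, with exact truth records:
a circular soma (radius 5 µm) with a nuclear disk, three gently wiggling
neurites (15–18 µm at 0.05 µm/px — chosen to fit a 1024² field; length
and pixel size scale freely), mRNA spots as analytic 2D Gaussians
(σ = 1.5 px, amplitude 0.5 on background 0.1 — evaluated, not convolved,
so truth coordinates are unambiguous), ribosomal puncta as σ = 2.5 px
blobs, mitochondria as rotated anisotropic Gaussians (2.0 × 0.5 µm), and
additive Gaussian noise (SD 0.05 by default, i.e. spot amplitude = 10×
noise; Poisson noise behind a flag — the camera model of the source
experiments is not published, so the simple additive model is the
default). Spots keep a ≥6 px mutual separation so planted counts are
recoverable exactly at zero noise.

Colocalization is planted by centering `round(f·n_target)` target
objects within 1 px of distinct mRNA spots and keeping the rest ≥12 px
clear of every mRNA spot, so the planted fraction is the only overlap
source. With equally many target objects as mRNA spots (the default),
the planted fraction equals the fraction of mRNA spots with a partner —
exactly what the mRNA-referenced pipeline estimates. What the generator
does **not** emulate: 3D PSFs, autofluorescence structure, mitochondrial
movement, chromatic shifts, or density gradients along neurites. Passing
the recovery tests therefore demonstrates the correctness of the
measurement chain, not robustness to every real-microscopy artifact.

Synthetic assay tables follow the same pattern: Ct tables plant log2
enrichments as cycle shifts (Ct = baseline − shift + noise), and count
tables draw multinomial reads with neurite weights scaled by planted
ratios over a background of unit-ratio genes (compositional bias <≈2% at
the defaults).

## qPCR arithmetic

ΔCt is the difference of compartment means, paired by replicate when ids
align (the policy is recorded). The summary 2^−ΔΔCt exponentiates the
*mean* ΔΔCt — the geometric mean of per-replicate enrichments — which
makes self-normalization exactly 1 and target/reference swaps exact
reciprocals; per-replicate values are available for arithmetic mean ±
SEM summaries. Oligo tables are cleaned of whitespace and zero-width
typographic separators on load (published tables contain them).

## Statistics

All tests are two-sided. Kruskal–Wallis uses the tie-corrected H with a
χ²(k−1) p-value; an all-tied sample degenerates to H = 0, p = 1 by
convention. Dunn's z uses the pooled-rank variance with the tie term
`Σ(t³−t)/(12(N−1))`. The rank-sum test enumerates the exact null
distribution (subset-sum dynamic programming over ranks) when the
combined sample has ≤20 untied observations, and otherwise uses the
tie-corrected normal approximation without continuity correction; the
two-sided p doubles the smaller tail, capped at 1. The t test is
Welch's — the source experiments say only "t test", and unequal variances
are the safer default. "Holm–Bonferroni" and "Holm" name the same
step-down procedure. Adjustments clip to [0, 1] and enforce the
step-down/step-up monotonicity. Implementations are from first
principles; scipy/statsmodels appear only as cross-checks in the tests.

Type-I calibration is verified on 2000 null simulations (normal samples,
20 + 20 for the rank-sum, 3 × 25 for Kruskal–Wallis; the group sizes are
where the asymptotic χ² approximation is well-centered) with an
acceptance band of [0.035, 0.065] at α = 0.05.

## Problem sizes and determinism

Default verification scenes are 1024² px (51.2 µm field) with 100 mRNA
spots; unit tests use 512² scenes with 60 spots. The planted-recovery
battery runs 20 scenes (4 seeds × 5 planted fractions) and the
three-condition design 10 cells per condition. Every random draw flows
from a single `numpy` Generator seeded from the caller, so scenes,
tables and pipeline bundles are bit-reproducible; pipeline runs write a
manifest with the full config, seed and input hashes.

## Known limitations

- Neurites within a cell are treated as independent observations, as in
  the source analyses; no mixed-effects modeling of the
  neurite-within-cell nesting.
- Colocalization is scored on 2D projections; cross-plane overlap in
  full 3D is out of scope.
- CLAHE equivalence to specific desktop implementations, deconvolution,
  and detector-array ("Airyscan"-style) processing are out of scope.
- The overlap estimate has a chance floor set by target-object area
  fraction; at the default densities it is ≈1–2% of reference objects,
  far below the 50%-overlap criterion's planted effects, but dense real
  images warrant a chance-level control (e.g. channel rotation).
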