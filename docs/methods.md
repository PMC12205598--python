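# Methods

This note documents the models, parameter choices and known limitations of
`paraloc`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic screen generator

The generator emulates a reciprocal paralog deletion screen: each pair
(A, B) contributes four strains (A-GFP in wild-type or *bΔ* background, and
vice versa), imaged as `n_fields` fields per condition in `n_replicates`
replicates, with 50–100 cells per field on a 512×512 px canvas by default —
the acquisition geometry of high-content yeast screens (four fields per
well, fifty to a hundred cells each, three replicates).

**Cells** are non-overlapping ellipses (semi-major axis 12–16 px, aspect
0.75–1) placed by rejection sampling; a configurable fraction
(`clump_fraction`, default 0.1) is placed deliberately touching to exercise
watershed splitting. Pixels claimed by two stencils go to the nearer
center; contact lines between labels are darkened to rim intensity, since
adjoining cells remain separated by their walls. Coordinates are 0-based
(row, col); masks use 0 = background.

**Compartment templates** are parametric geometry rather than learned
textures, so ground truth is analytic: cytoplasmic fill; a nuclear disk
(normalized radius ≤ 0.45, baseline 0.08 outside — placing > 70 % of signal
mass in the disk); an ER ring (0.68 ≤ r ≤ 0.90, > 2× interior contrast); an
off-center vacuolar blob; 4–7 punctae. A thin rim (r ≥ 0.92) at 5 % of
local intensity models the dark cell wall. Every template is normalized to
unit mean over the stencil, so **relocalization (template mixing) conserves
total fluorescence** and the abundance and localization axes of the planted
truth are orthogonal by construction.

**Effects.** A deletion-background condition multiplies expected intensity
by `effect_abundance` and/or mixes a fraction `effect_relocalization` of
the signal into a target compartment's template. The default planted truth
gives one member of each effect pair a 2× abundance increase plus a milder
(0.35) relocalization toward its partner's compartment, and the other
member a pure 0.6 relocalization; controls stay null. The combination
mirrors the common co-occurrence of abundance and localization changes on
real screens and reflects a genuine property of the score discussed under
*Limitations*.

**Noise** is Poisson shot noise on expected counts plus Gaussian read noise
(sd 5) on a constant background offset (100 counts) — the standard simple
fluorescence statistics. The microscope's true background level and noise
spectrum are unknown; these are free parameters chosen once.

**Networks.** Synthetic PPI/GI tables plant (when enabled) a higher
expected shared-interactor count (Poisson mean 8 vs 1), a higher direct-edge
probability and a strong negative within-pair genetic interaction
(ε ≈ −0.45, p < 0.04) for pairs containing a redistributed protein, so
network-feature comparisons have a detectable signal; with the association
off, all pairs are exchangeable.

## Segmentation

Soft targets follow the published encoding exactly: per-stencil erosion
with the minimal 4-neighbor cross, Euclidean distance transform of the
eroded map, clipped at 20 px and divided by 20 (the divisor makes the
maximum exactly 1; the source text says only "scaled between 0 and 1"), then
`0.8·binary + 0.2·scaled`. Flat-field background is the per-pixel median
over the image collection, subtracted with clipping at zero (negatives are
not meaningful counts). Normalization is `ln(x+1)` then per-image
standardization; constant images raise a typed error and are excluded by
callers with a logged reason.

The probability-map model is a contract (`predict_proba_map(image) ->
[0,1]` map of the input shape, honoring reflection padding to divisibility
by 32). The default trainable backend is a logistic-regression pixel
classifier — i.e. trained under binary cross-entropy — on a multiscale
feature stack (raw intensity, Gaussian blurs at σ = 1, 2, 4, 8, gradient
magnitude and Laplacian at σ = 2). The unsmoothed channel is load-bearing:
the 2–4 px gaps between touching cells vanish under σ ≥ 1 smoothing, and
without them the seeds merge. Training labels are the eroded-foreground
pixels of the soft target, so inter-cell gaps are labeled background and
predictions dip there. An untrained intensity/Otsu fallback serves quick
runs. A convolutional encoder–decoder would be the natural heavier backend;
the pixel classifier meets the same contract at desk scale.

Instances: connected components (4-connectivity) of `p ≥ 0.8` seed a
watershed on `−p` constrained to `p ≥ 0.5`; foreground unreachable from any
seed is discarded (the alternative — keeping unseeded foreground as extra
objects — would admit objects the model never confidently saw); areas
outside [256, 8192] px are removed; labels are consecutive. Seeds touching
the image border are kept; edge-cell handling belongs to the compartment
validation stage, where it is specified.

## Per-cell features

Frames are 64×64, centered on the rounded instance centroid, reflection
padded within 32 px of a border (excluding border cells would bias screens
toward sparse fields). Embedding frames come from the normalized image —
matching the order of the training pipeline — while raw
(background-subtracted, unlogged) frames are kept separately for abundance.

Morphology features are the ten standard region properties (area, convex
area, equivalent diameter, perimeter, eccentricity, major/minor axis
lengths, solidity, orientation, Euler number).

**Deterministic embedding (default).** 128 structured coordinates: 16
intensity summaries (mean, sd, min, max, eight quantiles, center/outer
means and their difference, median absolute deviation), a 48-bin radial
profile of the mean-subtracted frame, and a 64-bin histogram of
centred/sd-scaled intensities over [−4, 4]. All coordinates live on the
standardized-intensity scale, so no coordinate dominates the Euclidean
distance. The construction is seed-free and makes a constant intensity
shift move only the summary block; the identity serves as the (trivially
orthonormal) projection, keeping the intensity and shape channels
interpretable.

**Classifier embedding.** A multilayer perceptron (hidden layers 256 → 128,
ReLU, categorical cross-entropy) trained to classify frames by protein on
wild-type-background frames only — deletion backgrounds are rejected at the
API so the embedding space is defined on unperturbed cells. The embedding
is the 128-unit penultimate activation. Frames are 2×2 average-pooled
before the MLP at desk scale.

## Redistribution analysis

No feature scaling precedes the Euclidean distance (Z-scoring is applied
only inside the PCA visualization). Cells are pooled across replicates
with equal weight per cell; replicate-level weighting is not used. The ROC
threshold search uses midpoints between consecutive sorted unique pooled
scores (avoiding the boundary ambiguity of "greater than" at observed
values), returns the smallest threshold achieving minimal FPR, breaking
ties toward maximal TPR, and reports FPR/FNR/TPR at the chosen point. The
full-scale screen's published operating point (4.73) is stored as a
reference constant for report annotation only and is never recomputed from
synthetic data. PC signs follow a fixed convention (largest-|loading|
positive) so reruns are identical.

## Abundance

The statistical unit is the cell (per-cell mean raw frame intensity),
pooled across replicates; the unit is exposed as a config option since the
original description does not state it. Scores use a pseudocount of 1
before log2. Classification gates on BH-adjusted q (< 0.05) with
|log2fc| ≥ 0.2; the rule is sometimes stated with a raw p in this field,
so both p and q are recorded, but the FDR-adjusted value defines the class.
Groups with fewer than 3 cells yield a missing p, excluded from the BH
family. Fully tied samples return p = 1.

## Paralog calls

Relocalization annotations (destination compartment) are an explicit input
— visual inspection on real data, generator truth on synthetic data — the
redistribution score is intentionally non-directional and the package does
not infer destinations from embeddings. A destination equal to the
protein's own wild-type compartment is rejected as inconsistent.
Percentages are rounded half-up to integer percent. Roster filtering is
pairwise: both members of a quality-flagged pair leave together.

## Network association

GI subsets: lenient (p < 0.05), intermediate (p < 0.05, |ε| > 0.08),
stringent (p < 0.05, ε > 0.16 or ε < −0.12), synthetic-lethal (p < 0.05,
ε < −0.35); they nest by construction. Median splits assign
equal-to-median cases to "low" and log them, since "fewer or more than the
median" leaves equality unassigned. Disconnected or absent genes map to
path class "1+" with a missing length. The Fisher odds ratio is the sample
OR (ad/bc), infinite when only bc = 0 and undefined (missing) on a zero
margin. Localization sets from multiple sources are unioned; provenance
precedence is not modeled.

## Compartment validation

The background intensity of an image — undefined in the source description
— is the median over non-cell pixels, logged per image. Quantiles use
linear interpolation on sorted intensities. The 0.973/0.975 quantile gap is
preserved verbatim: pixels between the two cut-offs stay unassigned. The
background-QC multiplier (mean ± k·sd, sample sd) defaults to k = 1 and is
configurable. The default two-channel fixture renders 30 large cells
(radius 36–44 px) per 896×896 field, one field per strain per replicate,
three replicates — roughly 50 quantifiable cells per strain per replicate
after edge removal and the 100-ER-pixel filter, matching the scale of the
validation experiment it emulates.

## Problem sizes and determinism

The default screen (`demo_design`) is 6 effect pairs + 2 random-pair
controls × 2 backgrounds × 3 replicates × 4 fields at 60–90 cells per field
(384 fields, ≈ 25,000 cells), chosen so the full pipeline runs in a few
minutes on one CPU while leaving ≈ 850 cells per condition — enough that
centroid sampling noise sits well below the planted effects. All
randomness flows from a single integer seed through `SeedSequence` spawns;
identical (design, truth, seed) triples give bit-identical images, tables
and scores.

## Limitations

* **Per-image standardization cancels pure brightness changes in the
  embedding.** If foreground contrast dominates the image variance, the
  standardized foreground level is nearly invariant to a global intensity
  scaling, so a pure abundance change moves the embedding centroid only
  weakly — the redistribution score detects relocalization strongly and
  pure abundance changes poorly. The abundance axis is therefore
  quantified separately on raw frames (where a planted 2× effect is
  recovered as log2fc ≈ 1), and the default planted truth pairs abundance
  effects with a mild relocalization. Real screens show the same
  asymmetry: abundance-only responders near the detection threshold are
  the dominant false-negative class.
* Synthetic cells are convex ellipses without buds, vacuole texture or
  autofluorescence gradients; passing tests demonstrate the pipeline's
  correctness and calibration on known ground truth, not performance on
  real micrographs.
* The pixel-classifier segmenter has no learned shape prior; on real data
  with debris or uneven illumination a convolutional model behind the same
  contract would be preferred.
* The generator's noise model ignores detector gain variation, vignetting
  beyond the static background, and focus drift.
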