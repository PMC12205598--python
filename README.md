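# paraloc

Single-cell imaging quantification of how a GFP-tagged protein's subcellular
distribution changes when its paralog is deleted.

## The problem

After a whole-genome duplication, many yeast gene pairs (paralogs) survive
with partially overlapping functions. When one member of a pair is deleted,
its sister protein may respond by **compensation** — increasing in abundance
or relocalizing into the lost paralog's subcellular compartment — or by
**dependency** — decreasing in abundance or relocalizing to a compartment
that is neither its own nor its paralog's. `paraloc` implements a
high-content microscopy analysis that detects and classifies these responses
from single-cell fluorescence images of GFP-tagged proteins imaged in
wild-type and paralog-deletion backgrounds, and relates them to
protein-protein (PPI) and genetic-interaction (GI) network features.

The raw images of such screens are rarely public, so the package includes a
first-class synthetic-screen generator that renders fields of elliptical
cells with parametric compartment patterns (cytoplasmic fill, nuclear disk,
ER ring, vacuolar blob, punctae), Poisson-plus-Gaussian noise, and *planted*
abundance and relocalization effects — giving every pipeline stage exact
ground truth.

## The method

1. **Segmentation.** Instance masks are encoded into soft targets
   `T = 0.8·binary + 0.2·clip(EDT, 20)/20` (eroded with the 4-neighbor
   cross), so object borders sit at 0.8 and centers at 1. Images are
   flat-field corrected by the per-pixel median across the screen,
   transformed `x' = ln(x+1)` and standardized per image to mean 0, sd 1.
   A trainable pixel classifier produces a cell-probability map; connected
   components of `p ≥ 0.8` seed a watershed constrained to `p ≥ 0.5`, and
   objects outside 256–8192 px are removed.
2. **Per-cell features.** Each cell yields a 64×64 frame centered on its
   centroid (reflection-padded at borders), ten standard morphology
   features, and a 128-dimensional embedding. Two embedding backends share
   one interface: a deterministic handcrafted featurizer (default) and a
   trainable protein classifier read out at its 128-unit penultimate layer.
3. **Redistribution score.** For protein *g*, with per-condition centroids
   `c_WT(g), c_Δ(g)` (arithmetic means of the 128 features over all cells
   pooled across replicates),

   `score(g) = ‖ c_WT(g) − c_Δ(g) ‖₂`

   The classification threshold is selected by ROC analysis against
   random-pair negative controls: the smallest candidate threshold achieving
   minimal false-positive rate. A PCA view of Z-scored features is provided
   for visualization only.
4. **Abundance.** The abundance score is the mean raw pixel intensity over
   all frame pixels in a condition; the relative change is
   `log2fc = log₂(score_Δ+1) − log₂(score_WT+1)`, tested per protein by a
   two-sided Mann-Whitney U on per-cell means, BH-corrected; classes are
   increase (`log2fc ≥ 0.2, q < 0.05`), decrease (`≤ −0.2, q < 0.05`), ns.
5. **Calls and summaries.** Abundance increase → compensation, decrease →
   dependency; relocalization into the paralog's compartment → compensation,
   elsewhere → dependency. Pair- and screen-level summaries count
   reciprocal vs single-responder pairs and the fractions of redistributed
   proteins that relocalized, changed abundance, or both.
6. **Network association.** Redistribution scores are compared between bins
   defined by shared PPIs (median split), shortest path (1 vs 1+), GI
   subsets (lenient `p<0.05`; intermediate `+|ε|>0.08`; stringent
   `+(ε>0.16 ∨ ε<−0.12)`; synthetic-lethal `+ε<−0.35`), with Mann-Whitney U
   tests; colocalization uses the Jaccard index (≥ 50 on a 0–100 scale) and
   private-interactor enrichment uses Fisher's exact test.
7. **Compartment validation.** A two-channel (GFP + ER-marker) quantifier:
   edge cells within the median major-axis length of the border are removed,
   outlier-background images are discarded (mean ± sd per replicate), and
   within each cell marker pixels ≥ the 0.975 intensity quantile are ER,
   < the 0.973 quantile cytoplasmic; cells with < 100 ER pixels are
   discarded. Normalized abundance = median intensity / image background.

## Worked example

```python
from paraloc.pipeline import run_screen

result = run_screen(seed=1)          # 6 effect pairs + 2 random-pair controls
print(result.threshold)
print(result.scores.head(3).to_string(index=False))
print(result.pair_counts)
```

```
ThresholdResult(threshold=0.287, fpr=0.0, fnr=0.0, tpr=1.0)
protein  n_cells_wt  n_cells_del    score  threshold  flag_redistributed
   P00a         860          808 0.897863   0.287416                True
   P00b         848          823 1.279139   0.287416                True
   P01a         838          823 0.672293   0.287416                True
{'reciprocal': 6, 'single': 0, 'none': 2}
```

Reading the output: every protein in the six effect pairs scores above the
ROC threshold (the four random-pair control proteins set the operating
point, here with zero false positives), so all six pairs are reciprocally
responsive; the per-protein abundance table in `result.abundance` recovers
the planted 2× abundance effects as `log2fc ≈ 1.0`.

The command-line interface exposes the same stages
(`paraloc simulate | segment | features | score | abundance | call |
network | compartments | report`), e.g.:

```bash
paraloc --seed 1 report --out results/demo
```

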