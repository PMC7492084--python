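# barrelkit

Quantitative analysis toolkit for studies of layer-4 (L4) identity and
barrel-map organization in rodent somatosensory cortex, of the kind used
to characterize the role of the transcription factor RORβ.  It
re-implements, as a tested and reusable Python library, three analysis
tracks that such studies combine:

1. **Fluorescence quantification of barrel maps.**  From tangential
   sections stained for thalamocortical afferents (VGLUT2) or cell bodies
   (Nissl), with hand-drawn ROIs over 5–6 barrels, an enclosing ROI over
   the surrounding septa, and optional background ROIs, it computes the
   barrel–septa segregation statistic

   ```
   contrast = (barrel − septa) / (barrel + septa)
   ```

   where the septa mean is derived from *integrated* intensities
   (enclosing total minus the barrel ROI totals, divided by the septa
   pixel area), absolute intensities are normalized to background ROIs,
   and section values are averaged per animal.  RNAscope puncta are
   associated with the nearest cell centroid, tallied per cell, and
   averaged per layer per image, then per animal.

2. **Motif-instance calling with exact p-values and cross-validation.**
   A position weight matrix (PWM) is scored as a log2-odds sum against a
   0-order background; the score threshold realizing a motif p-value of
   10⁻⁴ is computed *exactly* by dynamic programming over the discretized
   null score distribution, and both strands are scanned.  Instances
   found by two scanner configurations are cross-validated, keeping only
   occurrences whose start and end coordinates agree within 1 bp.

3. **Enrichment statistics against shuffled controls.**  Control regions
   are produced by length-preserving uniform shuffling of ATAC peaks over
   the gap-free genome.  Motif enrichment in differential peaks uses a
   two-sided Fisher exact test against control regions (odds ratio
   `(a·d)/(b·c)`).  For differentially expressed genes (DEGs, defined by
   |fold change| ≥ 2 and adjusted p < 0.01), a motif is *reported* only
   when two Fisher tests are simultaneously significant at p < 0.03:
   enrichment in ATAC peaks near DEG transcription start sites (TSSs)
   over control regions, and enrichment of DEGs with a nearby motif over
   control genes (expressed above 5 TPM and never differential).  A
   layer-identity overrepresentation test asks whether e.g. down-regulated
   genes are concentrated among L4-specific genes.

Because the original imaging and sequencing data require animals or a
GEO download, every stage ships with a **synthetic-data generator** that
emits datasets with planted, known truth (true contrast, planted motif
instances, planted differential structure, Poisson puncta rates), so the
whole pipeline is testable at desk scale.

## Worked example

```python
import pandas as pd
from barrelkit import synthgen, imagequant, regenrich, statcore

# --- barrel-septa contrast on a synthetic section -----------------------
spec = synthgen.BarrelImageSpec(intensity_barrel=200, intensity_septa=100,
                                noise_sd=10, blur_sigma_px=1, seed=7)
img, truth = synthgen.simulate_barrel_image(spec)
m = imagequant.quantify_section(img, truth.roi_set, channel="VGLUT2")
print(f"true contrast     {truth.true_contrast:.4f}")
print(f"measured contrast {m.contrast:.4f}")

# --- layer overrepresentation on a planted expression table -------------
table, _ = synthgen.simulate_expression_table(synthgen.ExpressionTruthSpec(seed=7))
deg = pd.Series(statcore.apply_deg_criteria(table["lfc_P30"], table["padj_P30"]),
                index=table.index)
res = regenrich.layer_overrepresentation(
    table.index[table["layer"] == "L4"], table.index[deg == "down"], table.index)
print(f"L4 genes down-regulated: {100*res.fraction:.0f}%  "
      f"OR={res.odds_ratio:.1f}  p={res.p_value:.2e}")
```

prints

```
true contrast     0.3333
measured contrast 0.3173
L4 genes down-regulated: 28%  OR=33.2  p=5.52e-29
```

The measured contrast sits within 0.02 of the planted truth — the small
deficit is the partial-volume effect of the 1 px blur at barrel edges —
and the planted L4-specific down-regulation (26% of L4 genes plus ~1%
background) is recovered with a large odds ratio by the Fisher test.

A command-line interface mirrors the library:

```bash
barrelkit simulate image --seed 1 --outdir out/
barrelkit quantify barrels --image out/image.tif --rois out/roi_labels.tif --out section.tsv
barrelkit scan --fasta genome.fa --pwm motif.jaspar --scanner A --out a.bed
barrelkit xval --a a.bed --b b.bed --slack 1 --out xval.bed
barrelkit shuffle --peaks peaks.bed --genome sizes.tsv --gaps gaps.bed --seed 1 --out controls.bed
barrelkit enrich regions --targets peaks.bed --controls controls.bed --instances xval.bed --out enrich.tsv
```

## Layout

```
src/barrelkit/
  synthgen.py    synthetic images, genomes, expression tables, puncta (+ truth)
  imagequant.py  ROI measurement, contrast, normalization, puncta tallies
  motifscan.py   PWM log-odds scanning, exact p-value DP, cross-validation
  regenrich.py   shuffled controls, Fisher enrichment, TSS windows, layer test
  statcore.py    Fisher exact, Welch t, ANOVA, Benjamini–Hochberg, DEG rule
  cli.py         thin click front end (`barrelkit …`)
docs/methods.md  model assumptions, parameter choices, limitations
```
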