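# tfscape

Integrative regulatory-genomics analysis of two-condition transcription-factor
binding: differential ChIP-signal peak classes, nearest-TSS gene annotation,
footprinted-motif co-occurrence statistics, oriented composite-motif spacing,
and expression integration — with a synthetic-landscape generator that plants
ground truth for every stage.

## Who this is for

Groups studying how a perturbation (for instance, blocking AP-1 DNA binding
with a dominant-negative FOS peptide in differentiating hemogenic endothelium)
reshapes the binding landscape of a second factor such as TEAD4, and how those
binding changes propagate to gene expression. The package takes the outputs of
standard upstream processing — peak/summit BED files, per-condition tag
positions, DNaseI footprint intervals, a genome FASTA, PWMs and log2
expression tables — and implements the downstream comparative statistics.

## The statistics at its core

**Differential-binding classes.** Per-condition tags are counted in 50-bp bins
over ±1000 bp around each peak summit, normalized to tags-per-10-million, and
ranked by log2 fold change (condition B over A, with a pseudocount). Peaks
split into three classes at a ±1 log2 cutoff:

    class 1 (lost)    log2FC ≤ −1
    class 2 (shared)  −1 < log2FC < 1
    class 3 (gained)  log2FC ≥ 1

**Footprint co-occurrence z-scores.** For motifs *A*, *B*, the observed
statistic is the number of occupied (footprint-overlapping) hit pairs with
center distance ≤ 50 bp in the foreground footprints. The null draws 1000
equally sized, without-replacement subsamples of background regions and
recounts; the score is

    z(A, B) = (observed − mean_bg) / sd_bg.

Motif ordering for display comes from average-linkage hierarchical clustering
of the z matrix.

**Oriented composite spacing.** Every anchor-motif hit is aligned by its
reading direction and distances to nearby partner-motif hits are histogrammed
(anchor end → partner start by default, start → start as an option). A
composite motif appears as a sharp mode — e.g. a TEAD–AP-1 composite with a
7-bp spacer.

**Gene integration.** Nearest-TSS annotation links peaks to genes; a two-fold
(inclusive) filter on replicate-mean log2 contrasts finds differential genes;
k-means (Lloyd, best of 10 restarts) clusters expression profiles; Wilcoxon
rank-sum tests (exact for small groups) compare expression fold changes
between peak classes. Interval-overlap significance uses the hypergeometric
upper tail.

## Worked example

```bash
tfscape all --outdir demo --seed 4
cat demo/report.txt
```

runs the whole pipeline on a simulated landscape (1000 peaks at 30% lost /
65% shared / 5% gained, a TEAD–AP-1 composite planted at a 7-bp spacer in 80%
of foreground footprints, and a −1.5 log2 expression effect on lost-class
genes) and prints:

```
# tfscape report

## Peak classes (1 lost / 2 shared / 3 gained)
class 1: 300 peaks (30.0%)
class 2: 650 peaks (65.0%)
class 3: 50 peaks (5.0%)

## Top co-occurring motif pairs (bootstrap z)
AP1 - TEAD: z = 75.54

## Composite spacing
modal oriented distance = 7 bp (139 pairs, end_to_start convention)

## Expression clusters
cluster 0: 74 genes
...
differential genes (>= 2-fold): 137
```

The recovered class fractions equal the planted proportions, the designated
motif pair tops the co-occurrence matrix by a wide margin, and the modal
oriented distance equals the planted 7-bp spacer. `tfscape --show-defaults`
lists every default with its provenance; individual stages run as
subcommands (`simulate`, `classify`, `annotate`, `scan`, `cooccur`,
`spacing`, `cluster-expr`, `report`).

The same analyses are available as library calls:

```python
from tfscape import (LandscapeSpec, simulate_all, summit_matrix,
                     fold_change_classify)

ls = simulate_all(LandscapeSpec(seed=4))
table = fold_change_classify(summit_matrix(ls.peaks, ls.tags), "A", "B")
print(table["class"].value_counts())   # 1: 300, 2: 650, 3: 50
```

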