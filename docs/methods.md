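# Methods

This note documents the models, conventions and numerical choices behind
tfscape, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and interval algebra

All intervals are 0-based, half-open (BED convention); the BED
reader/writer is faithful for the first six columns plus an optional
seventh integer column carrying the summit offset from `start`. A peak's
reference point is its summit when present, else `floor((start+end)/2)`.

Nearest-gene annotation assigns each peak the gene whose TSS minimizes the
absolute distance to the reference point; ties break to the lower TSS
coordinate, then the lexicographically smaller symbol, so assignments are
deterministic. The signed distance is positive when the reference point
lies downstream of the TSS in the gene's reading direction (`ref − tss`
for + genes, `tss − ref` for − genes). Peaks on chromosomes without genes
are flagged unassigned rather than erroring — real annotations routinely
miss scaffolds.

Overlap significance models interval overlap as a hypergeometric draw:
`population_size` slots, `|a|` marked, `|b|` drawn, upper-tail p at the
observed overlap `k = min(a-hits, b-hits)` (the min guarantees
`k ≤ min(|a|,|b|)` under many-to-one overlaps). The population size is the
caller's to choose; `default_population_size` offers one declared
convention — effective genome length divided by the mean interval width of
the two sets — because the upstream literature delegates this choice to a
package without stating it. The p-value is therefore comparable only
within a fixed population convention.

## Signal quantification and the three-class split

Tags are single-bp positions; counts are taken in uniform `bin_width`
(default 50 bp) bins spanning ±`flank` (default 1000 bp) around the
reference point, half-open per bin, so a tag exactly at the summit falls
in the center-right bin. Region totals are scaled to tags-per-10-million
using each condition's full library size — a deliberate, simple stand-in
for the normalization an external counting tool would apply. A pseudocount
(default 1.0 on the normalized scale) stabilizes low counts:

    log2FC = log2((B_norm + c) / (A_norm + c))

Classes: 1 (lost) at `log2FC ≤ −cutoff`, 3 (gained) at `≥ +cutoff`,
2 (shared) strictly between; the boundary belongs to the extreme classes
so "shared" is an open interval. Default cutoff 1.0 log2 units. The table
is sorted by increasing log2FC with a 0-based rank. Note that global
normalization shifts all fold changes slightly when the two libraries
differ in size (e.g. when many peaks are lost); with the default ±1 cutoff
and the planted ±3 log2 effects this shift (~0.1 log2) is immaterial, but
at cutoffs close to the planted effect size it would matter.

## PWM scanning

Log-odds in bits from counts with a pseudocount:
`log2(((n_bj + c)/(N_j + 4c)) / bg_b)`. Scanning scores every window on
both strands and reports hits at `threshold × max_score` (default 0.8);
windows containing non-ACGT characters are skipped, and reverse-strand
hits are reported at the + strand leftmost coordinate. At the default
threshold and with the sharply peaked bundled matrices, scanning is
effectively consensus matching; the threshold is configurable because real
count matrices are softer. JASPAR-format matrices are parsed with
biopython.

The two bundled matrices (`ap1_synthetic.jaspar`, `tead_synthetic.jaspar`)
are synthetic count tables shaped like the AP-1 (TGACTCA) and TEAD
(GGAATG) consensus sequences — stand-ins for demonstration and simulation,
not database matrices.

## Co-occurrence bootstrap

A hit is "occupied" when its match overlaps a footprint interval. The
observed statistic for a motif pair counts occupied hit pairs with
center-to-center distance ≤ `window` (default 50 bp) — pairs of hits, not
footprints, a declared convention. The null resamples `|fg|` background
regions without replacement, `n_subsamples` (default 1000) times,
recounting pairs among hits overlapping the sampled regions ("equally
sized" = same region count, not the same total bp). Then
`z = (obs − mean)/sd`; when `sd = 0`, `z = 0` if the observation equals
the mean and is flagged infinite otherwise. Display order comes from
average-linkage hierarchical clustering (Euclidean) of the z rows.

Two properties of this design matter for interpretation:

- The subsample variance underestimates the across-experiment variance of
  a foreground-sized region set by the finite-population factor
  `(1 − |fg|/|bg|)`; z-scores are close to calibrated only when the
  background is several times larger than the foreground. The defaults
  (300 foreground footprints, 2400 background regions) respect this, as
  does the biology being emulated, where the background open-chromatin
  compartment is much larger than the footprinted subset.
- Pairs sharing a motif are correlated through that motif's abundance, so
  the across-pair mean z inherits motif-abundance fluctuations of the one
  observed foreground. The generator therefore fixes each motif's
  occupancy count per compartment (see below); with Bernoulli per-region
  occupancy the per-pair z remains calibrated but the dataset-level mean z
  fluctuates more.

## Oriented spacing

For every anchor hit, each partner hit within `max_dist` (default 100 bp)
contributes one oriented distance. Default convention `end_to_start`:
`partner.start − anchor.end` for + anchors, mirrored
(`anchor.start − partner.end`) for − anchors; the alternative
`start_to_start` convention is a config switch, since figure legends and
methods sections in the literature disagree on the anchor. Under
`start_to_start` the mode shifts by exactly the anchor motif length. The
mode is the most frequent distance, ties broken to the smallest absolute
value; an empty histogram yields an explicitly undefined mode (`None`),
never 0. Spacing should be computed on occupied (footprinted) hits — the
pipeline's `spacing` stage filters to foreground footprints when they are
configured — because genome-wide hit lists are dominated by background
matches of short motifs.

## Expression integration

Replicates are averaged (arithmetic mean of log2 values) before
contrasts; a moderated-statistics microarray pipeline is out of scope and
this simple stand-in is the declared model. Differential calls are
inclusive at the fold threshold (`|log2FC| ≥ log2(f)`, default f = 2).
k-means is Lloyd's algorithm (scikit-learn), Euclidean, best of 10
restarts, deterministic given the seed; `distance="correlation"`
row-standardizes first, which orders points identically to
centered-correlation distance. Class-versus-rest comparisons use the
two-sided Wilcoxon rank-sum, exact when both groups have ≤ 12
observations and the values are tie-free, normal approximation otherwise;
classes with fewer than 3 genes are excluded with a warning.

## The synthetic landscape generator

The generator emits exactly the formats the analysis consumes (FASTA,
BED with summit column, tag TSVs, expression and metadata TSVs) plus a
JSON ground-truth sidecar, and is byte-deterministic given the spec and
its mandatory seed.

What it emulates, and the default study conditions:

- **Peaks and tags** — 1000 peaks of 400 bp on 2 chromosomes, laid out so
  ±1000 bp windows never overlap. True classes in proportions
  (0.30, 0.65, 0.05), realised as a ×2^(−3) / ×1 / ×2^(+3) rate multiplier
  on condition B. Tag counts per peak are Poisson (mean 200 in condition
  A); positions are Gaussian around the summit (s.d. 150 bp), truncated to
  the window. Background sequence is i.i.d. uniform ACGT.
- **Motifs** — consensus instances planted near summits with
  class-conditional probabilities (AP-1-like motif: 0.9 in lost peaks,
  0.05 elsewhere; TEAD-like motif: 0.9 in all classes). Planting the
  consensus (rather than matrix-sampled variants) keeps every planted
  instance recoverable by threshold scanning, so ground truth stays exact.
- **Footprints** — foreground footprints and background regions share one
  width (200 bp) and one base occupancy rate (0.30), and the fg/bg split
  of the region pool is itself random, so with no planted pairs the two
  compartments are exchangeable and the z-scores are null-calibrated. Each
  motif's occupied-region count per compartment is fixed at
  `round(rate × n)`; only which regions are occupied is random (a
  footprint catalog has fixed observed occupancy counts). Designated
  pairs additionally co-occur in a stated fraction (default 0.8) of
  foreground regions at the composite spacing, 7 bp by default, with
  centered jitter: the nominal spacing carries 60% of the mass and the
  ±noise alternatives share the rest, so the planted spacing is the
  preferred arrangement, as in a real composite element.
- **Expression** — 7 stages × 2 conditions × 2 replicates. Genes (500)
  sit 200 bp from distinct peak summits so nearest-TSS annotation links
  each gene to its peak. log2 values are a per-cluster stage profile
  (7 clusters, profile s.d. 2.0 around a baseline of 6) plus a −1.5 log2
  perturbation effect on lost-class-linked genes in the affected stages,
  plus Gaussian replicate noise (s.d. 0.25).

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level sequencing (no FASTQ, no errors, no
fragment-length or duplicate structure), input/IgG background, soft motif
instances and cooperative/overlapping sites, GC or mappability biases,
correlated replicate structure, probe-level microarray noise, and any
peak- or footprint-calling uncertainty (peaks and footprints are taken as
given). Recovery rates on this generator are upper bounds on real-data
performance.

## Problem sizes and determinism

The test suite and the acceptance script run simulations at the scales
above (up to 1000 peaks, 105 motif pairs × 1000 bootstrap subsamples, 500
composite pairs, 500 genes), chosen so every planted effect is detected
with wide margins while a full run stays in the tens of seconds. All
randomness flows from `numpy.random.default_rng` seeded from a single
integer; the three simulation stages use fixed offsets from the spec seed
so stages are independently reproducible. The CLI records parameters,
seeds and input checksums in `pipeline.log`, and identical config + seed
reproduce every output byte for byte.

## Known limitations

- The hypergeometric overlap p-value depends strongly on the population
  convention; compare p-values only under a fixed convention.
- Tags-per-10-million normalization couples fold changes across peaks
  through the library totals (no trimmed-mean or loess alternative).
- The co-occurrence bootstrap assumes background regions are exchangeable
  units; it does not model within-region hit clustering beyond what the
  subsampling captures.
- The exact rank-sum path refuses ties (it falls back to the normal
  approximation), so borderline p-values near the exact/asymptotic
  boundary can shift by more than rounding.
- `venn_counts` supports 2–3 sets only; no genomic-feature (promoter /
  exon / intron) breakdown is provided, as that needs a full gene model.
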