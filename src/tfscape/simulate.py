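"""Synthetic regulatory landscapes with planted ground truth.

The generator emits everything the analysis stages consume — genome
FASTA, summit-annotated peak BED, per-condition tag TSVs, footprint and
background-region BEDs, expression and metadata TSVs — together with a
JSON ground-truth sidecar, so every stage can be validated against what
was planted.

The planted structure mirrors a two-condition differential-binding
experiment: peaks carry a true class (lost / shared / gained) realised
as a Poisson rate multiplier on the perturbed condition; a
lineage-specific motif is planted preferentially in lost peaks while a
second motif occurs in all classes; foreground footprints carry a
designated motif pair at a fixed oriented spacing in a stated fraction
of regions while background regions see motifs only at a base rate; and
gene expression follows per-cluster stage profiles with a negative
perturbation effect confined to genes linked to lost peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, GeneAnnotation, write_gene_annotation
from .motifs import PWM, read_jaspar
from .expression import ExpressionMatrix
from . import signal as signal_mod

_BASE_ASCII = np.array([65, 67, 71, 84], dtype=np.uint8)  # ACGT


def default_pwms(pseudocount: float = 1.0) -> dict[str, PWM]:
    """The two bundled synthetic motif models: an AP-1-like TGACTCA
    7-mer and a TEAD-like GGAATG 6-mer, built from synthetic count
    matrices (stand-ins shaped like the real consensus sequences, not
    any database matrix)."""
    pwms: dict[str, PWM] = {}
    for fname in ("ap1_synthetic.jaspar", "tead_synthetic.jaspar"):
        ref = resources.files("tfscape.data") / fname
        with resources.as_file(ref) as path:
            pwms.update(read_jaspar(path, pseudocount=pseudocount))
    return pwms


def random_motifs(n: int, length: int = 8, seed: int | None = None,
                  dominant: float = 85.0, minor: float = 5.0) -> dict[str, PWM]:
    """Synthetic sharply-peaked PWMs with random consensus sequences,
    for calibration experiments needing many distinct motifs."""
    rng = np.random.default_rng(seed)
    out: dict[str, PWM] = {}
    for i in range(n):
        cons = rng.integers(0, 4, size=length)
        counts = np.full((4, length), minor)
        counts[cons, np.arange(length)] = dominant
        name = f"M{i:02d}"
        out[name] = PWM(name, counts)
    return out


@dataclass
class LandscapeSpec:
    """Parameters of the synthetic landscape; ``seed`` is mandatory.

    ``class_proportions`` orders (lost, shared, gained) and must sum
    to 1; ``effect_log2fc`` is the magnitude of the planted signal
    change in the extreme classes.  ``motif_plant_probs`` maps motif
    name -> {class: probability of planting an instance near the
    summit}.  ``cooccur_pairs`` maps an ordered (anchor, partner) motif
    pair to the probability that a foreground footprint carries the
    composite at ``composite_spacing`` +/- ``spacing_noise`` bp.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int | None = None  # derived from the layout when None
    n_peaks: int = 1000
    peak_width: int = 400
    class_proportions: tuple[float, float, float] = (0.30, 0.65, 0.05)
    effect_log2fc: float = 3.0
    tags_per_peak: float = 200.0
    tag_sd: float = 150.0
    flank: int = 1000
    motif_plant_probs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "AP1": {1: 0.90, 2: 0.05, 3: 0.05},
            "TEAD": {1: 0.90, 2: 0.90, 3: 0.90},
        }
    )
    composite_spacing: int = 7
    spacing_noise: int = 1
    n_footprints_fg: int = 300
    n_bg_regions: int = 2400
    region_width: int = 200
    cooccur_pairs: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("TEAD", "AP1"): 0.8}
    )
    motif_base_prob: float = 0.30
    n_genes: int = 500
    expr_clusters: int = 7
    stages: tuple[str, ...] = ("FLK1", "5h", "day1", "SM", "HE1", "HE2", "HP")
    conditions: tuple[str, str] = ("untreated", "DOX")
    dox_affected_stages: tuple[str, ...] = ("day1", "SM", "HE1")
    dox_effect: float = -1.5
    n_replicates: int = 2
    replicate_noise_sd: float = 0.25
    cluster_profile_sd: float = 2.0
    pwms: dict[str, PWM] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ValueError("class_proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class_proportions must be non-negative")
        for n in (self.n_peaks, self.n_footprints_fg, self.n_bg_regions,
                  self.n_genes, self.n_chroms, self.n_replicates):
            if n < 0:
                raise ValueError("counts must be >= 0")
        for pair, p in self.cooccur_pairs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"co-occurrence probability for {pair} not in [0,1]")
        if self.n_genes > self.n_peaks:
            raise ValueError("n_genes cannot exceed n_peaks (genes are peak-linked)")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.pwms is None:
            self.pwms = default_pwms()

    # --- genome layout -----------------------------------------------------

    @property
    def peak_step(self) -> int:
        return 2 * self.flank + self.peak_width

    @property
    def region_step(self) -> int:
        return self.region_width + 300

    def _layout(self) -> tuple[int, int, int]:
        """(peaks per chrom, regions per chrom, required chrom length)."""
        ppc = -(-self.n_peaks // self.n_chroms) if self.n_peaks else 0
        n_regions = self.n_footprints_fg + self.n_bg_regions
        rpc = -(-n_regions // self.n_chroms) if n_regions else 0
        margin = 2000
        need = margin + ppc * self.peak_step + 5000 + rpc * self.region_step + margin
        return ppc, rpc, need

    def required_chrom_length(self) -> int:
        return self._layout()[2]

    def resolved_chrom_length(self) -> int:
        need = self.required_chrom_length()
        if self.chrom_length is None:
            return need
        if self.chrom_length < need:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for layout "
                f"(need >= {need})"
            )
        return self.chrom_length


@dataclass
class GroundTruth:
    """What was planted, for end-to-end validation."""

    peak_class: list[int] = field(default_factory=list)  # per peak, 1/2/3
    peak_log2fc: list[float] = field(default_factory=list)
    motif_instances: list[dict] = field(default_factory=list)
    fg_cooccur: list[dict] = field(default_factory=list)  # per fg region
    gene_cluster: dict[str, int] = field(default_factory=dict)
    gene_peak: dict[str, int] = field(default_factory=dict)  # gene -> peak idx
    gene_class: dict[str, int] = field(default_factory=dict)
    gene_dox_log2fc: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        gt = cls(**d)
        gt.gene_cluster = {k: int(v) for k, v in gt.gene_cluster.items()}
        gt.gene_peak = {k: int(v) for k, v in gt.gene_peak.items()}
        gt.gene_class = {k: int(v) for k, v in gt.gene_class.items()}
        return gt


@dataclass
class Landscape:
    """In-memory simulated landscape plus ground truth."""

    spec: LandscapeSpec
    genome: dict[str, np.ndarray]  # chrom -> int8 base codes
    peaks: IntervalSet
    tags: dict[str, dict[str, np.ndarray]]  # condition -> chrom -> positions
    truth: GroundTruth
    fg_footprints: IntervalSet | None = None
    bg_regions: IntervalSet | None = None
    expression: ExpressionMatrix | None = None
    genes: list[GeneAnnotation] = field(default_factory=list)

    def sequences(self) -> dict[str, str]:
        return {c: _decode(v) for c, v in self.genome.items()}

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact the analysis stages consume; returns the
        path of each named output."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.sequences(), paths["genome"])
        paths["peaks"] = outdir / "peaks.bed"
        self.peaks.to_bed(paths["peaks"], summit_column=True)
        for cond, tagdict in self.tags.items():
            p = outdir / f"tags_{cond}.tsv"
            signal_mod.write_tags(tagdict, p)
            paths[f"tags_{cond}"] = p
        if self.fg_footprints is not None:
            paths["fg_footprints"] = outdir / "footprints_fg.bed"
            self.fg_footprints.to_bed(paths["fg_footprints"])
        if self.bg_regions is not None:
            paths["bg_regions"] = outdir / "regions_bg.bed"
            self.bg_regions.to_bed(paths["bg_regions"])
        if self.expression is not None:
            paths["expression"] = outdir / "expression.tsv"
            paths["expression_meta"] = outdir / "expression_meta.tsv"
            self.expression.to_tsv(paths["expression"], paths["expression_meta"])
        if self.genes:
            paths["genes"] = outdir / "genes.tsv"
            write_gene_annotation(self.genes, paths["genes"])
        paths["truth"] = outdir / "ground_truth.json"
        self.truth.to_json(paths["truth"])
        return paths


def _decode(codes: np.ndarray) -> str:
    return _BASE_ASCII[codes].tobytes().decode("ascii")


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def _consensus_instance(pwm: PWM) -> np.ndarray:
    """The PWM's consensus sequence as base codes.  Planting the
    consensus keeps every planted instance recoverable by threshold
    scanning, so ground truth stays exact."""
    return pwm.counts.argmax(axis=0).astype(np.int8)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.int8)


def _plant(genome: dict[str, np.ndarray], chrom: str, start: int,
           pwm: PWM, strand: str, rng: np.random.Generator,
           truth: GroundTruth) -> None:
    inst = _consensus_instance(pwm)
    if strand == "-":
        inst = _revcomp_codes(inst)
    genome[chrom][start:start + pwm.length] = inst
    truth.motif_instances.append(
        {"chrom": chrom, "start": int(start), "end": int(start + pwm.length),
         "motif": pwm.name, "strand": strand}
    )


def _allocate_classes(n: int, proportions: Sequence[float],
                      rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of exact class counts, shuffled."""
    raw = np.asarray(proportions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i % len(base)]] += 1
    labels = np.repeat(np.arange(1, len(base) + 1), base)
    rng.shuffle(labels)
    return labels


def simulate_regulatory_landscape(spec: LandscapeSpec) -> Landscape:
    """Genome + peaks + two-condition tags with planted classes.

    Background sequence is i.i.d. uniform over ACGT.  Each peak gets a
    true class realised as a log2 rate multiplier on condition B
    (lost: -effect, shared: 0, gained: +effect); per-condition tag
    counts are Poisson and tag positions Gaussian around the summit
    (s.d. ``tag_sd``), truncated to the +/-flank window.  Motifs are
    planted near summits per the class-conditional probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    ppc, _, _ = spec._layout()
    clen = spec.resolved_chrom_length()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    genome = {
        c: rng.integers(0, 4, size=clen, dtype=np.int8) for c in chroms
    }
    truth = GroundTruth()

    classes = _allocate_classes(spec.n_peaks, spec.class_proportions, rng)
    lfc_by_class = {1: -spec.effect_log2fc, 2: 0.0, 3: spec.effect_log2fc}

    peaks: list[GenomicInterval] = []
    tags: dict[str, dict[str, list[int]]] = {
        cond: {c: [] for c in chroms} for cond in ("A", "B")
    }
    margin = 2000
    for i in range(spec.n_peaks):
        chrom = chroms[i // ppc]
        slot = i % ppc
        start = margin + slot * spec.peak_step + spec.flank
        summit_off = spec.peak_width // 2
        peak = GenomicInterval(chrom, start, start + spec.peak_width,
                               summit=summit_off, name=f"peak{i:05d}")
        peaks.append(peak)
        cls = int(classes[i])
        lfc = lfc_by_class[cls]
        truth.peak_class.append(cls)
        truth.peak_log2fc.append(lfc)
        summit = peak.reference_point

        rate = {"A": spec.tags_per_peak, "B": spec.tags_per_peak * 2.0**lfc}
        for cond in ("A", "B"):
            n_tags = rng.poisson(rate[cond])
            if n_tags == 0:
                continue
            pos = rng.normal(summit, spec.tag_sd, size=n_tags)
            pos = np.clip(np.rint(pos), summit - spec.flank,
                          summit + spec.flank - 1).astype(np.int64)
            tags[cond][chrom].extend(pos.tolist())

        # class-conditional motif planting near the summit
        offset = -40
        for motif, probs in spec.motif_plant_probs.items():
            pwm = spec.pwms[motif]
            if rng.random() < probs.get(cls, 0.0):
                strand = "+" if rng.random() < 0.5 else "-"
                jitter = int(rng.integers(0, 10))
                _plant(genome, chrom, summit + offset + jitter, pwm, strand,
                       rng, truth)
            offset += 40

    tag_arrays = {
        cond: {c: np.sort(np.asarray(v, dtype=np.int64))
               for c, v in byc.items() if v}
        for cond, byc in tags.items()
    }
    return Landscape(spec=spec, genome=genome,
                     peaks=IntervalSet(peaks, label="peaks"),
                     tags=tag_arrays, truth=truth)


def _spacing_jitter(noise: int, rng: np.random.Generator) -> int:
    """Centered jitter on the composite spacing: the nominal spacing is
    the preferred (modal) arrangement, carrying 60% of the mass, with
    the remainder spread evenly over the +/-noise alternatives."""
    if noise <= 0:
        return 0
    offsets = [d for d in range(-noise, noise + 1) if d != 0]
    probs = [0.4 / len(offsets)] * len(offsets) + [0.6]
    return int(rng.choice(offsets + [0], p=probs))


def simulate_footprints(landscape: Landscape) -> Landscape:
    """Plant footprint / background regions with motif co-occurrence.

    Foreground footprints and background regions share one width and
    one base motif-planting rate, so under a null spec (all planted
    co-occurrence probabilities zero) the two compartments are
    exchangeable and downstream z-scores are calibrated.  Designated
    motif pairs additionally co-occur at the composite spacing in the
    stated fraction of foreground regions only.
    """
    spec = landscape.spec
    rng = np.random.default_rng(spec.seed + 1)
    ppc, rpc, _ = spec._layout()
    chroms = list(landscape.genome)
    margin = 2000
    zone_start = margin + ppc * spec.peak_step + 5000

    n_total = spec.n_footprints_fg + spec.n_bg_regions
    regions: list[GenomicInterval] = []
    for i in range(n_total):
        chrom = chroms[i // rpc]
        slot = i % rpc
        start = zone_start + slot * spec.region_step
        regions.append(GenomicInterval(chrom, start, start + spec.region_width,
                                       name=f"region{i:05d}"))
    # random fg/bg split keeps the compartments exchangeable under null
    idx = rng.permutation(n_total)
    fg_idx = set(idx[: spec.n_footprints_fg].tolist())

    motif_names = list(spec.pwms)
    spans: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_total)}

    def _free_slot(region: GenomicInterval, i: int, length: int) -> int | None:
        if region.end - length <= region.start:
            return None
        for _ in range(20):
            s = int(rng.integers(region.start, region.end - length))
            if all(s + length <= a or s >= b for a, b in spans[i]):
                return s
        return None

    # planted composite pairs (foreground only)
    pair_flags: dict[int, dict[str, bool]] = {i: {} for i in range(n_total)}
    for i, region in enumerate(regions):
        if i not in fg_idx:
            continue
        for (anchor, partner), p in spec.cooccur_pairs.items():
            hit = rng.random() < p
            pair_flags[i][f"{anchor}|{partner}"] = bool(hit)
            if not hit:
                continue
            apwm, ppwm = spec.pwms[anchor], spec.pwms[partner]
            spacing = spec.composite_spacing + _spacing_jitter(
                spec.spacing_noise, rng
            )
            total = apwm.length + spacing + ppwm.length
            s = _free_slot(region, i, total)
            if s is None:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                _plant(landscape.genome, region.chrom, s, apwm, "+", rng,
                       landscape.truth)
                _plant(landscape.genome, region.chrom,
                       s + apwm.length + spacing, ppwm, "+", rng,
                       landscape.truth)
            else:
                _plant(landscape.genome, region.chrom, s, ppwm, "-", rng,
                       landscape.truth)
                _plant(landscape.genome, region.chrom,
                       s + ppwm.length + spacing, apwm, "-", rng,
                       landscape.truth)
            spans[i].append((s, s + total))

    # base occupancy: each motif gets a fixed number of occupied regions
    # per compartment (round(rate x n)); only which regions are occupied
    # is random.  Fixing the marginal counts keeps null z-scores from
    # inheriting motif-abundance fluctuations shared across pairs.
    compartments = [
        sorted(fg_idx),
        [i for i in range(n_total) if i not in fg_idx],
    ]
    for motif in motif_names:
        pwm = spec.pwms[motif]
        for comp in compartments:
            k = round(spec.motif_base_prob * len(comp))
            chosen = rng.choice(len(comp), size=k, replace=False)
            for ci in chosen:
                i = comp[int(ci)]
                region = regions[i]
                s = _free_slot(region, i, pwm.length)
                if s is None:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                _plant(landscape.genome, region.chrom, s, pwm, strand, rng,
                       landscape.truth)
                spans[i].append((s, s + pwm.length))

    fg = [r for i, r in enumerate(regions) if i in fg_idx]
    bg = [r for i, r in enumerate(regions) if i not in fg_idx]
    for i, region in enumerate(regions):
        if i in fg_idx:
            landscape.truth.fg_cooccur.append(
                {"region": region.name, **pair_flags[i]}
            )
    landscape.fg_footprints = IntervalSet(fg, label="fg_footprints")
    landscape.bg_regions = IntervalSet(bg, label="bg_regions")
    return landscape


def simulate_expression(landscape: Landscape) -> Landscape:
    """Gene expression linked to peak classes.

    Genes are placed with their TSS a short distance from distinct peak
    summits (so nearest-gene annotation links each gene to its peak).
    log2 values follow a per-cluster stage profile; genes linked to
    lost (class-1) peaks receive the negative perturbation effect in
    the affected stages; Gaussian replicate noise on top.
    """
    spec = landscape.spec
    rng = np.random.default_rng(spec.seed + 2)
    if spec.n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    n_stages = len(spec.stages)
    profiles = rng.normal(6.0, spec.cluster_profile_sd,
                          size=(spec.expr_clusters, n_stages))
    peak_order = rng.permutation(len(landscape.peaks))[: spec.n_genes]
    clusters = rng.integers(0, spec.expr_clusters, size=spec.n_genes)

    genes: list[GeneAnnotation] = []
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    cond_a, cond_b = spec.conditions
    truth = landscape.truth

    gene_names = [f"gene{i:04d}" for i in range(spec.n_genes)]
    for gi, (pi, cl) in enumerate(zip(peak_order, clusters)):
        peak = landscape.peaks[int(pi)]
        tss = peak.reference_point + 200
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_names[gi], peak.chrom, tss, strand))
        truth.gene_cluster[gene_names[gi]] = int(cl)
        truth.gene_peak[gene_names[gi]] = int(pi)
        cls = truth.peak_class[int(pi)]
        truth.gene_class[gene_names[gi]] = cls
        truth.gene_dox_log2fc[gene_names[gi]] = (
            spec.dox_effect if cls == 1 else 0.0
        )

    dox_lfc = np.array([truth.gene_dox_log2fc[g] for g in gene_names])
    base = profiles[clusters]  # genes x stages
    for si, stage in enumerate(spec.stages):
        affected = stage in spec.dox_affected_stages
        for cond in spec.conditions:
            effect = dox_lfc if (cond == cond_b and affected) else 0.0
            for rep in range(1, spec.n_replicates + 1):
                sample = f"{stage}_{cond}_r{rep}"
                noise = rng.normal(0.0, spec.replicate_noise_sd,
                                   size=spec.n_genes)
                columns[sample] = base[:, si] + effect + noise
                meta_rows.append(
                    {"sample": sample, "stage": stage, "condition": cond,
                     "replicate": rep}
                )

    values_df = pd.DataFrame(columns, index=gene_names)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    landscape.expression = ExpressionMatrix(values=values_df, metadata=meta)
    landscape.genes = genes
    return landscape


def simulate_all(spec: LandscapeSpec) -> Landscape:
    """Run all three simulation stages."""
    ls = simulate_regulatory_landscape(spec)
    simulate_footprints(ls)
    simulate_expression(ls)
    return ls
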