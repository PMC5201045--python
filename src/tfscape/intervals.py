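"""Genomic interval algebra: BED I/O, overlaps, nearest-TSS annotation.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A peak's reference point is its summit when one is
known (stored as an offset from ``start``) and the integer midpoint
``floor((start + end) / 2)`` otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic range with optional summit, score and strand.

    ``summit`` is the offset (bp) of the point of maximal signal from
    ``start``; it must lie inside the interval.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not (0 <= self.summit < len(self)):
            raise ValueError(
                f"summit offset {self.summit} outside interval of length {len(self)}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def reference_point(self) -> int:
        """Summit position if known, else the integer midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by
    (chrom, start).  Overlap within a set is permitted; merging is an
    explicit operation the caller performs if wanted."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def _tree(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for idx, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices of member intervals overlapping [start, end) on chrom."""
        tree = self._tree().get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(start, end))

    @property
    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    # --- BED I/O (bit-faithful on the first six columns) ------------------

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "") -> "IntervalSet":
        """Read BED3/BED6, with an optional 7th integer column giving the
        summit offset from ``start``."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 and f[3] != "." else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
                summit = int(f[6]) if len(f) > 6 and f[6] != "." else None
                ivs.append(
                    GenomicInterval(chrom, start, end, summit=summit, score=score,
                                    strand=strand, name=name)
                )
        return cls(ivs, label=label or Path(path).stem)

    def to_bed(self, path: str | Path, summit_column: bool = False) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                cols = [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else "0",
                    iv.strand if iv.strand is not None else ".",
                ]
                if summit_column:
                    cols.append(str(iv.summit) if iv.summit is not None else ".")
                fh.write("\t".join(cols) + "\n")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a 4-column TSV (gene, chrom, tss, strand); unique gene symbols."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            g, chrom, tss, strand = line.split("\t")[:4]
            if g in seen:
                raise ValueError(f"duplicate gene symbol {g!r} in annotation")
            seen.add(g)
            genes.append(GeneAnnotation(g, chrom, int(tss), strand))
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# --------------------------------------------------------------------------
# Overlap report
# --------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Result of :func:`intersect_sets`.

    ``pairs`` holds (index in a, index in b) for every overlapping pair;
    the per-set hit counts are reported separately because they are not
    symmetric when set sizes differ (many-to-one overlaps).
    """

    pairs: list[tuple[int, int]]
    n_a_hit: int
    n_b_hit: int
    regions: IntervalSet

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def intersect_sets(a: IntervalSet, b: IntervalSet, min_overlap: int = 1) -> OverlapReport:
    """All overlapping pairs between two interval sets.

    An a-interval counts as overlapping when at least one b-interval
    shares ``min_overlap`` or more bp with it (and vice versa for b).
    The intersected regions (one per pair) are returned as a set.
    """
    if min_overlap < 0:
        raise ValueError(f"min_overlap must be >= 0, got {min_overlap}")
    min_overlap = max(min_overlap, 1)
    pairs: list[tuple[int, int]] = []
    regions: list[GenomicInterval] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    for i, iv in enumerate(a):
        for j in b.overlapping(iv.chrom, iv.start, iv.end):
            jv = b[j]
            if iv.overlap_len(jv) >= min_overlap:
                pairs.append((i, j))
                a_hit.add(i)
                b_hit.add(j)
                regions.append(
                    GenomicInterval(iv.chrom, max(iv.start, jv.start),
                                    min(iv.end, jv.end))
                )
    return OverlapReport(pairs=pairs, n_a_hit=len(a_hit), n_b_hit=len(b_hit),
                         regions=IntervalSet(regions, label="intersection"))


# --------------------------------------------------------------------------
# Nearest-gene annotation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NearestGene:
    """Nearest-TSS assignment for one peak.

    ``distance`` is signed in the gene's reading direction: positive when
    the peak's reference point lies downstream of the TSS.  ``None`` for
    both fields flags a peak on a chromosome without genes.
    """

    gene: str | None
    distance: int | None

    @property
    def assigned(self) -> bool:
        return self.gene is not None


def annotate_nearest_gene(
    peaks: IntervalSet, genes: Sequence[GeneAnnotation]
) -> list[NearestGene]:
    """Assign each peak the gene with the TSS nearest its reference point.

    Ties on absolute distance go to the lower TSS coordinate, then to the
    lexicographically smaller gene symbol.  Peaks on chromosomes with no
    annotated gene are returned unassigned rather than raising.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # sort by (tss, gene) so np.searchsorted + local scan honors tie-breaks
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.gene))
    tss_arrays = {c: np.array([g.tss for g in gs]) for c, gs in by_chrom.items()}

    out: list[NearestGene] = []
    for peak in peaks:
        gs = by_chrom.get(peak.chrom)
        if not gs:
            out.append(NearestGene(None, None))
            continue
        ref = peak.reference_point
        tss = tss_arrays[peak.chrom]
        i = int(np.searchsorted(tss, ref))
        neighbors = [j for j in (i - 1, i) if 0 <= j < len(gs)]
        d_min = min(abs(ref - gs[j].tss) for j in neighbors)
        # all genes at exactly d_min (either side; several may share a TSS)
        cand: list[int] = []
        for target in (ref - d_min, ref + d_min):
            lo = int(np.searchsorted(tss, target, side="left"))
            hi = int(np.searchsorted(tss, target, side="right"))
            cand.extend(range(lo, hi))
        best = min((gs[j].tss, gs[j].gene, j) for j in cand)
        g = gs[best[2]]
        signed = ref - g.tss if g.strand == "+" else g.tss - ref
        out.append(NearestGene(g.gene, signed))
    return out


# --------------------------------------------------------------------------
# Venn partitions and overlap significance
# --------------------------------------------------------------------------

def venn_counts(sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, int]:
    """Exclusive/shared category counts for 2-3 labelled item sets.

    Returns a mapping from a frozenset of set labels (the category: which
    input sets an item belongs to) to the item count in that category.
    Categories partition each input, so per-set category counts sum back
    to set sizes.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"venn_counts supports 2-3 sets, got {len(sets)}")
    materialized = {k: set(v) for k, v in sets.items()}
    labels = list(materialized)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(materialized[k] for k in combo))
            outside = set.union(
                *(materialized[k] for k in labels if k not in combo), set()
            )
            counts[frozenset(combo)] = len(inside - outside)
    return counts


def default_population_size(a: IntervalSet, b: IntervalSet,
                            effective_genome_length: int) -> int:
    """Effective genome length divided by the mean interval width of the
    union of both sets, rounded — the number of interval-sized slots the
    genome offers.  A declared convention, configurable by the caller."""
    widths = [len(iv) for iv in a] + [len(iv) for iv in b]
    if not widths:
        raise ValueError("both interval sets are empty")
    return round(effective_genome_length / float(np.mean(widths)))


def overlap_significance(
    a: IntervalSet,
    b: IntervalSet,
    population_size: int,
    min_overlap: int = 1,
) -> float:
    """Hypergeometric upper-tail p-value of the observed overlap.

    Models |a| marked slots among ``population_size``, |b| drawn slots,
    and asks P(X >= k) where k is the observed overlap count (the smaller
    of the two per-set hit counts, so k <= min(|a|, |b|) always holds).
    """
    if population_size < max(len(a), len(b)):
        raise ValueError("population_size smaller than an interval set")
    if len(a) == 0 or len(b) == 0:
        return 1.0
    rep = intersect_sets(a, b, min_overlap=min_overlap)
    k = min(rep.n_a_hit, rep.n_b_hit)
    if population_size < len(a) + len(b) - k:
        raise ValueError(
            f"impossible configuration: population {population_size} < "
            f"|a| + |b| - k = {len(a) + len(b) - k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, population_size, len(a), len(b)))
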