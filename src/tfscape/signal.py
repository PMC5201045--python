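"""Summit-centered tag quantification and differential-binding classes.

Per-condition sequencing tags (single-bp positions) are counted in
uniform bins spanning a fixed flank either side of each region's
reference point.  Region totals, normalized to tags-per-10-million,
drive a log2 fold-change ranking and a three-class split:

    class 1 (lost):   log2fc <= -cutoff
    class 2 (shared): -cutoff < log2fc < +cutoff
    class 3 (gained): log2fc >= +cutoff

with the default cutoff at 1.0 log2 units.  Boundary values belong to
the extreme classes, so "shared" is an open interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet

#: tags-per-10-million scaling used before fold changes
NORM_SCALE = 1e7

TagDict = Mapping[str, np.ndarray]  # chrom -> sorted tag positions (bp)


def read_tags(path: str | Path) -> dict[str, np.ndarray]:
    """Read tag positions from a 2-column TSV (chrom, bp) or a BED of
    single-bp intervals (the start coordinate is used)."""
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            by_chrom.setdefault(f[0], []).append(int(f[1]))
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def write_tags(tags: TagDict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tags):
            for pos in tags[chrom]:
                fh.write(f"{chrom}\t{int(pos)}\n")


@dataclass
class SignalMatrix:
    """Binned tag counts around region reference points, per condition.

    ``counts[cond]`` has one row per region and one column per bin; bin j
    covers offsets ``[-flank + j*bin_width, -flank + (j+1)*bin_width)``
    relative to the reference point, so an offset of exactly 0 falls in
    the center-right bin.  ``library_size`` is the total tag count of
    each condition (all tags, not only those inside windows).
    """

    regions: IntervalSet
    bin_edges: np.ndarray  # offsets, length n_bins + 1
    counts: dict[str, np.ndarray]
    library_size: dict[str, int]

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def conditions(self) -> list[str]:
        return list(self.counts)

    def region_totals(self, cond: str) -> np.ndarray:
        return self.counts[cond].sum(axis=1)


def summit_matrix(
    regions: IntervalSet,
    tags_by_condition: Mapping[str, TagDict],
    flank: int = 1000,
    bin_width: int = 50,
) -> SignalMatrix:
    """Count tags in uniform bins over +/-flank around each reference point.

    Tag position arrays must be sorted per chromosome.  Windows running
    off a chromosome end simply collect zero tags there; no clipping of
    the bin grid is applied, so every row spans identical offsets.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    if bin_width <= 0 or flank % bin_width != 0:
        raise ValueError(
            f"flank ({flank}) must be a positive multiple of bin_width ({bin_width})"
        )
    for cond, tags in tags_by_condition.items():
        for chrom, pos in tags.items():
            arr = np.asarray(pos)
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"tags unsorted on {chrom} in condition {cond!r}")

    edges = np.arange(-flank, flank + bin_width, bin_width)
    n_bins = len(edges) - 1
    counts: dict[str, np.ndarray] = {}
    lib: dict[str, int] = {}
    for cond, tags in tags_by_condition.items():
        mat = np.zeros((len(regions), n_bins), dtype=np.int64)
        for i, iv in enumerate(regions):
            pos = tags.get(iv.chrom)
            if pos is None or len(pos) == 0:
                continue
            abs_edges = iv.reference_point + edges
            # half-open bins: count of pos in [edge_j, edge_{j+1})
            idx = np.searchsorted(pos, abs_edges, side="left")
            mat[i] = np.diff(idx)
        counts[cond] = mat
        lib[cond] = int(sum(len(v) for v in tags.values()))
    return SignalMatrix(regions=regions, bin_edges=edges, counts=counts,
                        library_size=lib)


def fold_change_classify(
    m: SignalMatrix,
    cond_a: str,
    cond_b: str,
    cutoff: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank regions by log2 fold change of B over A and split into the
    lost / shared / gained classes.

    Region totals are normalized to tags-per-10-million per condition,
    stabilized with a pseudocount, and the table is returned sorted by
    increasing log2fc with a ``rank`` column (0-based).  Columns:
    region, chrom, start, end, tags_a, tags_b, log2fc, class, rank.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    for cond in (cond_a, cond_b):
        if cond not in m.counts:
            raise KeyError(f"condition {cond!r} not in matrix")
        if m.library_size[cond] <= 0:
            raise ValueError(f"library size for {cond!r} is zero")
    tot_a = m.region_totals(cond_a) * NORM_SCALE / m.library_size[cond_a]
    tot_b = m.region_totals(cond_b) * NORM_SCALE / m.library_size[cond_b]
    log2fc = np.log2((tot_b + pseudocount) / (tot_a + pseudocount))
    cls = np.where(log2fc <= -cutoff, 1, np.where(log2fc >= cutoff, 3, 2))

    names = [
        iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        for iv in m.regions
    ]
    df = pd.DataFrame(
        {
            "region": names,
            "chrom": [iv.chrom for iv in m.regions],
            "start": [iv.start for iv in m.regions],
            "end": [iv.end for iv in m.regions],
            "tags_a": tot_a,
            "tags_b": tot_b,
            "log2fc": log2fc,
            "class": cls,
        }
    )
    df = df.sort_values("log2fc", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    return df


def write_classified_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def average_profile(
    m: SignalMatrix,
    groups: Mapping[int, Hashable] | Sequence[Hashable] | Callable[[int], Hashable],
    condition: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-group mean bin vectors (arithmetic mean of member rows).

    ``groups`` maps region index to a group label (mapping, sequence, or
    callable); every region must be grouped.  Returns, per condition, a
    DataFrame of groups x bins indexed by group label.
    """
    n = len(m.regions)
    if callable(groups):
        labels = [groups(i) for i in range(n)]
    elif isinstance(groups, Mapping):
        missing = [i for i in range(n) if i not in groups]
        if missing:
            raise ValueError(f"{len(missing)} regions without a group label")
        labels = [groups[i] for i in range(n)]
    else:
        if len(groups) != n:
            raise ValueError("group sequence length must equal region count")
        labels = list(groups)

    conditions = [condition] if condition is not None else m.conditions
    out: dict[str, pd.DataFrame] = {}
    label_arr = pd.Series(labels)
    for cond in conditions:
        mat = m.counts[cond]
        rows = {}
        for g, idx in label_arr.groupby(label_arr).groups.items():
            member = mat[np.asarray(idx)]
            if member.shape[0] == 0:
                raise ValueError(f"group {g!r} is empty")
            rows[g] = member.mean(axis=0)
        out[cond] = pd.DataFrame.from_dict(rows, orient="index")
    return out
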