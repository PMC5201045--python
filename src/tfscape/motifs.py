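"""PWM scanning, motif presence, footprint co-occurrence and spacing.

The co-occurrence statistic asks whether two transcription-factor
motifs are found occupied (footprinted) near each other more often
than chance: the observed count of occupied hit pairs within a short
window is compared against a bootstrap null built by repeatedly
subsampling an equal number of regions from a background compartment
and recounting.  The z-score is (observed - null mean) / null s.d.

The oriented spacing statistic aligns every anchor-motif hit by its
reading direction and histograms the distance to nearby partner-motif
hits; a composite motif shows up as a sharp mode (e.g. a 7 bp spacer
between a TEAD motif end and an AP-1 motif start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.cluster import hierarchy

from .intervals import GenomicInterval, IntervalSet

BASES = "ACGT"
_BASE_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

#: reverse-complement base permutation (A<->T, C<->G); N maps to itself
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, other=4."""
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PWM:
    """Position weight matrix with log-odds scoring.

    ``counts`` is a 4 x L array (rows A, C, G, T).  Column probabilities
    use a pseudocount: p[b][j] = (counts[b][j] + pc) / (colsum + 4 pc),
    and log-odds are log2(p / background) in bits.
    """

    def __init__(
        self,
        name: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 1.0,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4 or counts.ndim != 2 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")
        colsum = counts.sum(axis=0)
        if pseudocount <= 0 and np.any(colsum == 0):
            raise ValueError("all-zero column requires a positive pseudocount")
        self.name = name
        self.counts = counts
        self.background = bg
        self.pseudocount = float(pseudocount)
        probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
        self.log_odds = np.log2(probs / bg[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        """Best attainable log-odds score (sum of per-column maxima)."""
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def __repr__(self) -> str:
        return f"PWM({self.name!r}, L={self.length}, consensus={self.consensus})"


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> PWM:
    """Build a PWM (log-odds in bits) from a count matrix."""
    return PWM(name, counts, background=background, pseudocount=pseudocount)


def read_jaspar(path: str | Path, pseudocount: float = 1.0) -> dict[str, PWM]:
    """Read JASPAR-format count matrices into PWMs (keyed by motif name)."""
    out: dict[str, PWM] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            name = m.name or m.matrix_id
            out[name] = PWM(name, counts, pseudocount=pseudocount)
    return out


def write_jaspar(pwms: Mapping[str, PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, pwm in pwms.items():
            fh.write(f">{name} {name}\n")
            for b, row in zip(BASES, pwm.counts):
                fh.write(f"{b}  [ " + "  ".join(format(v, "g") for v in row) + " ]\n")


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM match; ``start`` is the leftmost + strand coordinate
    regardless of which strand matched, and ``end = start + L``."""

    chrom: str
    start: int
    end: int
    motif: str
    strand: str
    score: float

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float = 0.8,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Score every window on both strands; report hits at or above
    ``threshold`` times the PWM's maximum score.

    Windows containing any non-ACGT base are skipped.  Reverse-strand
    hits are reported at their + strand leftmost coordinate with
    strand '-'.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    L = pwm.length
    codes = encode_sequence(seq)
    if len(codes) < L:
        return []
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~np.any(win == 4, axis=1)
    cols = np.arange(L)
    # pad log-odds with a row for code 4 so invalid windows score safely
    lo = np.vstack([pwm.log_odds, np.zeros(L)])
    fwd = lo[win, cols].sum(axis=1)
    # reverse-complement scoring: complement rows, reverse columns
    lo_rc = np.vstack([pwm.log_odds[::-1, ::-1], np.zeros(L)])
    rev = lo_rc[win, cols].sum(axis=1)

    cut = threshold * pwm.max_score
    hits = [
        MotifHit(chrom, int(i), int(i) + L, pwm.name, "+", float(fwd[i]))
        for i in np.nonzero(valid & (fwd >= cut))[0]
    ] + [
        MotifHit(chrom, int(i), int(i) + L, pwm.name, "-", float(rev[i]))
        for i in np.nonzero(valid & (rev >= cut))[0]
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_genome(
    sequences: Mapping[str, str],
    pwms: Mapping[str, PWM],
    threshold: float = 0.8,
) -> dict[str, list[MotifHit]]:
    """Scan every chromosome with every PWM; hits keyed by motif name."""
    out: dict[str, list[MotifHit]] = {name: [] for name in pwms}
    for chrom, seq in sequences.items():
        for name, pwm in pwms.items():
            out[name].extend(scan_sequence(seq, pwm, threshold, chrom=chrom))
    return out


def write_hits_bed(hits: Mapping[str, list[MotifHit]], path: str | Path) -> None:
    """BED6 output: name = motif, score = bits x 100 rounded."""
    rows = sorted(
        (h for hs in hits.values() for h in hs),
        key=lambda h: (h.chrom, h.start, h.motif),
    )
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif}\t"
                f"{round(h.score * 100)}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path) -> dict[str, list[MotifHit]]:
    out: dict[str, list[MotifHit]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, motif, score, strand = line.split("\t")[:6]
            out.setdefault(motif, []).append(
                MotifHit(chrom, int(start), int(end), motif, strand,
                         float(score) / 100.0)
            )
    return out


def filter_occupied(
    hits: Mapping[str, Sequence[MotifHit]], regions: IntervalSet
) -> dict[str, list[MotifHit]]:
    """Restrict hit lists to occupied instances: hits whose match
    overlaps at least one interval of ``regions`` (e.g. footprints)."""
    return {
        motif: [h for h in hs if regions.overlapping(h.chrom, h.start, h.end)]
        for motif, hs in hits.items()
    }


def motif_presence_matrix(
    regions: IntervalSet, hits: Mapping[str, Sequence[MotifHit]]
) -> pd.DataFrame:
    """Boolean regions x motifs matrix: a cell is True iff at least one
    hit lies with its full match inside the region (flush edges count)."""
    mat = pd.DataFrame(
        False,
        index=range(len(regions)),
        columns=list(hits),
        dtype=bool,
    )
    for motif, hs in hits.items():
        for h in hs:
            for i in regions.overlapping(h.chrom, h.start, h.end):
                iv = regions[i]
                if h.start >= iv.start and h.end <= iv.end:
                    mat.at[i, motif] = True
    return mat


# --------------------------------------------------------------------------
# Footprint co-occurrence bootstrap
# --------------------------------------------------------------------------

@dataclass
class CooccurrenceResult:
    """Observed pair counts, bootstrap background moments and z-scores.

    All four matrices are symmetric DataFrames indexed by motif name.
    ``flagged`` marks pairs with zero background s.d. but an observed
    count off the background mean (z formally infinite).  ``order``
    is the motif ordering from average-linkage hierarchical clustering
    of the z matrix rows (Euclidean distance).
    """

    observed: pd.DataFrame
    bg_mean: pd.DataFrame
    bg_sd: pd.DataFrame
    z: pd.DataFrame
    flagged: pd.DataFrame
    order: list[str]

    @property
    def motifs(self) -> list[str]:
        return list(self.z.index)

    def pair(self, a: str, b: str) -> dict[str, float]:
        return {
            "observed": float(self.observed.at[a, b]),
            "bg_mean": float(self.bg_mean.at[a, b]),
            "bg_sd": float(self.bg_sd.at[a, b]),
            "z": float(self.z.at[a, b]),
        }


def _occupied_hit_arrays(
    hits: Mapping[str, Sequence[MotifHit]],
    regions: IntervalSet,
    motif_index: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten hits overlapping any region into parallel arrays:
    (chrom id, center, motif id, first overlapped region index)."""
    chrom_ids: dict[str, int] = {}
    chroms, centers, mids, rids = [], [], [], []
    for motif, hs in hits.items():
        mi = motif_index[motif]
        for h in hs:
            overlapped = regions.overlapping(h.chrom, h.start, h.end)
            if not overlapped:
                continue
            chroms.append(chrom_ids.setdefault(h.chrom, len(chrom_ids)))
            centers.append(h.center)
            mids.append(mi)
            rids.append(overlapped[0])
    return (
        np.asarray(chroms, dtype=np.int64),
        np.asarray(centers, dtype=float),
        np.asarray(mids, dtype=np.int64),
        np.asarray(rids, dtype=np.int64),
    )


def _pair_count_matrix(
    chroms: np.ndarray,
    centers: np.ndarray,
    mids: np.ndarray,
    n_motifs: int,
    window: float,
) -> np.ndarray:
    """Count unordered hit pairs with center distance <= window on the
    same chromosome, accumulated per motif pair (symmetric matrix)."""
    mat = np.zeros((n_motifs, n_motifs), dtype=np.int64)
    if len(centers) == 0:
        return mat
    order = np.lexsort((centers, chroms))
    c, x, m = chroms[order], centers[order], mids[order]
    n = len(x)
    # fold (chrom, center) into one sorted key with chromosomes spaced
    # further apart than the window, so a single searchsorted finds, for
    # each hit i, the partner range (i, hi): same chrom, center distance
    # <= window
    span = float(x.max() - x.min()) + 2.0 * window + 1.0
    key = x + c * span
    hi = np.searchsorted(key, key + window, side="right")
    counts = hi - np.arange(1, n + 1)
    total = int(counts.sum())
    if total == 0:
        return mat
    i_idx = np.repeat(np.arange(n), counts)
    j_idx = np.concatenate([np.arange(i + 1, h) for i, h in enumerate(hi) if h > i + 1])
    np.add.at(mat, (m[i_idx], m[j_idx]), 1)
    np.add.at(mat, (m[j_idx], m[i_idx]), 1)
    # self-pairs of the same motif were double-added; the diagonal holds
    # 2x the unordered count, halve it back
    np.fill_diagonal(mat, np.diag(mat) // 2)
    return mat


def cooccurrence_zscores(
    fg_footprints: IntervalSet,
    bg_regions: IntervalSet,
    hits: Mapping[str, Sequence[MotifHit]],
    window: int = 50,
    n_subsamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CooccurrenceResult:
    """Bootstrap z-scores for pairwise motif co-occurrence in footprints.

    A hit participates only if its match overlaps a foreground footprint
    (or, on the background side, a background region).  The observed
    statistic counts occupied hit pairs with center distance <= window;
    each of ``n_subsamples`` background draws takes a without-replacement
    sample of ``len(fg_footprints)`` background regions and recounts.
    Zero background s.d. yields z = 0 when the observation equals the
    background mean and is flagged (infinite) otherwise.
    """
    if n_subsamples < 2:
        raise ValueError(f"n_subsamples must be >= 2, got {n_subsamples}")
    if len(bg_regions) < len(fg_footprints):
        raise ValueError(
            f"background ({len(bg_regions)} regions) smaller than foreground "
            f"({len(fg_footprints)} footprints)"
        )
    if len(fg_footprints) == 0:
        raise ValueError("empty foreground footprint set")
    if rng is None:
        rng = np.random.default_rng(seed)

    names = list(hits)
    midx = {m: i for i, m in enumerate(names)}
    P = len(names)

    fgc, fgx, fgm, _ = _occupied_hit_arrays(hits, fg_footprints, midx)
    observed = _pair_count_matrix(fgc, fgx, fgm, P, window)

    bgc, bgx, bgm, bgr = _occupied_hit_arrays(hits, bg_regions, midx)
    n_draw = len(fg_footprints)
    n_bg = len(bg_regions)
    sums = np.zeros((P, P))
    sq = np.zeros((P, P))
    member = np.zeros(n_bg, dtype=bool)
    for _ in range(n_subsamples):
        chosen = rng.choice(n_bg, size=n_draw, replace=False)
        member[:] = False
        member[chosen] = True
        keep = member[bgr]
        cnt = _pair_count_matrix(bgc[keep], bgx[keep], bgm[keep], P, window)
        sums += cnt
        sq += cnt.astype(float) ** 2
    mean = sums / n_subsamples
    var = sq / n_subsamples - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
        flagged = (sd == 0) & (observed != mean)
        z = np.where(
            sd == 0,
            np.where(observed == mean, 0.0, np.inf * np.sign(observed - mean)),
            z,
        )

    def _df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=names, columns=names)

    order = _cluster_order(np.where(np.isfinite(z), z, 0.0), names)
    return CooccurrenceResult(
        observed=_df(observed.astype(float)),
        bg_mean=_df(mean),
        bg_sd=_df(sd),
        z=_df(z),
        flagged=_df(flagged),
        order=order,
    )


def _cluster_order(z: np.ndarray, names: list[str]) -> list[str]:
    """Motif ordering by average-linkage hierarchical clustering of the
    z matrix rows, Euclidean distance."""
    if len(names) < 3:
        return list(names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        link = hierarchy.linkage(z, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return [names[i] for i in leaves]


# --------------------------------------------------------------------------
# Oriented composite-motif spacing
# --------------------------------------------------------------------------

@dataclass
class SpacingResult:
    """Histogram of oriented anchor-to-partner distances.

    ``distances`` spans [-max_dist, max_dist]; ``counts`` aligns with it.
    ``mode`` is None when no partner fell within range of any anchor —
    an explicitly undefined mode, distinct from a mode at 0.
    """

    distances: np.ndarray
    counts: np.ndarray
    n_pairs: int

    @property
    def mode(self) -> int | None:
        if self.n_pairs == 0:
            return None
        best = self.counts.max()
        tied = self.distances[self.counts == best]
        return int(min(tied, key=lambda d: (abs(d), d)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distances, "count": self.counts})


def spacing_distribution(
    anchor_hits: Sequence[MotifHit],
    partner_hits: Sequence[MotifHit],
    max_dist: int = 100,
    anchor_convention: str = "end_to_start",
) -> SpacingResult:
    """Oriented distances from anchor hits to nearby partner hits.

    Every partner within ``max_dist`` of an anchor contributes one
    distance, measured in the anchor's reading direction.  With the
    ``end_to_start`` convention a + strand anchor measures partner
    start minus anchor end (mirrored for - strand anchors); the
    ``start_to_start`` convention measures start-to-start instead.
    """
    if anchor_convention not in ("end_to_start", "start_to_start"):
        raise ValueError(f"unknown anchor convention {anchor_convention!r}")
    by_chrom: dict[str, list[MotifHit]] = {}
    for p in partner_hits:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda h: h.start)
    starts = {c: np.array([p.start for p in ps]) for c, ps in by_chrom.items()}

    dists = np.arange(-max_dist, max_dist + 1)
    counts = np.zeros(len(dists), dtype=np.int64)
    n_pairs = 0
    for a in anchor_hits:
        ps = by_chrom.get(a.chrom)
        if not ps:
            continue
        arr = starts[a.chrom]
        # generous candidate window (partner lengths vary), exact filter below
        max_lp = max(p.end - p.start for p in ps)
        lo = int(np.searchsorted(arr, a.start - max_dist - max_lp - 1))
        hi = int(np.searchsorted(arr, a.end + max_dist + max_lp + 1))
        for p in ps[lo:hi]:
            if anchor_convention == "end_to_start":
                d = p.start - a.end if a.strand != "-" else a.start - p.end
            else:
                d = p.start - a.start if a.strand != "-" else a.end - p.end
            if -max_dist <= d <= max_dist:
                counts[d + max_dist] += 1
                n_pairs += 1
    return SpacingResult(distances=dists, counts=counts, n_pairs=n_pairs)
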