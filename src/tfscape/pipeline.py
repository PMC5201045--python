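"""Stage orchestration behind the command-line interface.

Each stage reads its inputs from the paths in the config, writes TSV or
BED outputs into the output directory, and appends a log record with
parameters, seed, input checksums and counts at every filter step.
``report`` aggregates the stage outputs into one human-readable text
file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from . import motifs as motif_mod
from . import signal as signal_mod
from . import simulate as sim_mod
from .config import AnalysisConfig
from .intervals import (
    IntervalSet,
    annotate_nearest_gene,
    intersect_sets,
    read_gene_annotation,
)

log = logging.getLogger("tfscape")


class MissingInputError(FileNotFoundError):
    """A stage input file named in the config does not exist."""


def _require(path: str, what: str) -> Path:
    if not path:
        raise MissingInputError(f"no path configured for {what}")
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"missing {what}: {p}")
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _log_inputs(stage: str, cfg: AnalysisConfig, paths: dict[str, Path]) -> None:
    for name, p in paths.items():
        log.info("%s: input %s = %s (sha256 %s)", stage, name, p, _sha256(p))
    log.info("%s: seed = %d", stage, cfg.seed)


def stage_simulate(cfg: AnalysisConfig, outdir: Path) -> dict[str, Path]:
    """Generate the synthetic landscape and point the config at it."""
    spec = sim_mod.LandscapeSpec(seed=cfg.seed,
                                 composite_spacing=7, spacing_noise=1)
    ls = sim_mod.simulate_all(spec)
    paths = ls.write_outputs(outdir / "simulated")
    cfg.genome = str(paths["genome"])
    cfg.peaks = str(paths["peaks"])
    cfg.tags_a = str(paths["tags_A"])
    cfg.tags_b = str(paths["tags_B"])
    cfg.fg_footprints = str(paths["fg_footprints"])
    cfg.bg_regions = str(paths["bg_regions"])
    cfg.expression = str(paths["expression"])
    cfg.expression_meta = str(paths["expression_meta"])
    cfg.genes = str(paths["genes"])
    log.info("simulate: %d peaks, %d fg footprints, %d bg regions, %d genes",
             len(ls.peaks), len(ls.fg_footprints), len(ls.bg_regions),
             len(ls.genes))
    return paths


def stage_classify(cfg: AnalysisConfig, outdir: Path) -> Path:
    peaks = IntervalSet.from_bed(_require(cfg.peaks, "peak BED"))
    tags = {
        "A": signal_mod.read_tags(_require(cfg.tags_a, "condition-A tags")),
        "B": signal_mod.read_tags(_require(cfg.tags_b, "condition-B tags")),
    }
    _log_inputs("classify", cfg, {"peaks": Path(cfg.peaks),
                                  "tags_a": Path(cfg.tags_a),
                                  "tags_b": Path(cfg.tags_b)})
    m = signal_mod.summit_matrix(peaks, tags, flank=cfg.flank,
                                 bin_width=cfg.bin_width)
    table = signal_mod.fold_change_classify(
        m, "A", "B", cutoff=cfg.class_cutoff, pseudocount=cfg.pseudocount
    )
    out = outdir / "classified_peaks.tsv"
    signal_mod.write_classified_table(table, out)
    counts = table["class"].value_counts().sort_index()
    log.info("classify: classes %s of %d peaks", counts.to_dict(), len(table))

    # map class labels back to matrix row order via region names
    names = [
        iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        for iv in peaks
    ]
    labels = table.set_index("region")["class"].loc[names].tolist()
    profiles = signal_mod.average_profile(m, labels)
    for cond, df in profiles.items():
        df.to_csv(outdir / f"profiles_{cond}.tsv", sep="\t",
                  float_format="%.4f")
    return out


def stage_annotate(cfg: AnalysisConfig, outdir: Path) -> Path:
    peaks = IntervalSet.from_bed(_require(cfg.peaks, "peak BED"))
    genes = read_gene_annotation(_require(cfg.genes, "gene annotation TSV"))
    _log_inputs("annotate", cfg, {"peaks": Path(cfg.peaks),
                                  "genes": Path(cfg.genes)})
    hits = annotate_nearest_gene(peaks, genes)
    out = outdir / "nearest_genes.tsv"
    with open(out, "w") as fh:
        fh.write("peak\tchrom\tstart\tend\tgene\tdistance\n")
        for iv, ng in zip(peaks, hits):
            fh.write(
                f"{iv.name or '.'}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{ng.gene or 'NA'}\t{ng.distance if ng.distance is not None else 'NA'}\n"
            )
    n_assigned = sum(1 for ng in hits if ng.assigned)
    log.info("annotate: %d/%d peaks assigned a nearest gene",
             n_assigned, len(peaks))
    return out


def stage_scan(cfg: AnalysisConfig, outdir: Path) -> Path:
    sequences = sim_mod.read_fasta(_require(cfg.genome, "genome FASTA"))
    _log_inputs("scan", cfg, {"genome": Path(cfg.genome)})
    pwms = sim_mod.default_pwms()
    hits = motif_mod.scan_genome(sequences, pwms, threshold=cfg.scan_threshold)
    out = outdir / "motif_hits.bed"
    motif_mod.write_hits_bed(hits, out)
    log.info("scan: %s hits at threshold %.2f",
             {m: len(h) for m, h in hits.items()}, cfg.scan_threshold)

    if cfg.peaks and Path(cfg.peaks).exists():
        peaks = IntervalSet.from_bed(cfg.peaks)
        presence = motif_mod.motif_presence_matrix(peaks, hits)
        presence.index = [iv.name or i for i, iv in enumerate(peaks)]
        presence.to_csv(outdir / "motif_presence.tsv", sep="\t")
    return out


def _load_hits(outdir: Path) -> dict[str, list[motif_mod.MotifHit]]:
    path = outdir / "motif_hits.bed"
    if not path.exists():
        raise MissingInputError(f"missing motif hits: {path} (run 'scan' first)")
    return motif_mod.read_hits_bed(path)


def stage_cooccur(cfg: AnalysisConfig, outdir: Path) -> Path:
    fg = IntervalSet.from_bed(_require(cfg.fg_footprints, "foreground footprint BED"))
    bg = IntervalSet.from_bed(_require(cfg.bg_regions, "background region BED"))
    hits = _load_hits(outdir)
    _log_inputs("cooccur", cfg, {"fg": Path(cfg.fg_footprints),
                                 "bg": Path(cfg.bg_regions)})
    res = motif_mod.cooccurrence_zscores(
        fg, bg, hits, window=cfg.cooccur_window,
        n_subsamples=cfg.n_subsamples, seed=cfg.seed,
    )
    out = outdir / "cooccurrence_z.tsv"
    res.z.loc[res.order, res.order].to_csv(out, sep="\t", float_format="%.4f")
    res.observed.to_csv(outdir / "cooccurrence_observed.tsv", sep="\t",
                        float_format="%.1f")
    log.info("cooccur: %d motifs, max off-diagonal z = %.2f",
             len(res.motifs), _max_offdiag(res.z))
    return out


def _max_offdiag(z: pd.DataFrame) -> float:
    arr = z.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, -np.inf)
    arr = arr[np.isfinite(arr)]
    return float(arr.max()) if arr.size else float("nan")


def stage_spacing(cfg: AnalysisConfig, outdir: Path) -> Path:
    hits = _load_hits(outdir)
    if cfg.fg_footprints and Path(cfg.fg_footprints).exists():
        # spacing is a statement about occupied (footprinted) motifs
        fg = IntervalSet.from_bed(cfg.fg_footprints)
        hits = motif_mod.filter_occupied(hits, fg)
    for motif in (cfg.anchor_motif, cfg.partner_motif):
        if motif not in hits or not hits[motif]:
            raise MissingInputError(f"no hits for motif {motif!r} in motif_hits.bed")
    res = motif_mod.spacing_distribution(
        hits[cfg.anchor_motif], hits[cfg.partner_motif],
        max_dist=cfg.spacing_max_dist, anchor_convention=cfg.spacing_anchor,
    )
    out = outdir / "spacing_histogram.tsv"
    res.to_frame().to_csv(out, sep="\t", index=False)
    log.info("spacing: %d pairs, mode = %s (%s convention)",
             res.n_pairs, res.mode, cfg.spacing_anchor)
    return out


def stage_cluster_expr(cfg: AnalysisConfig, outdir: Path) -> Path:
    expr = expr_mod.ExpressionMatrix.from_tsv(
        _require(cfg.expression, "expression TSV"),
        _require(cfg.expression_meta, "expression metadata TSV"),
    )
    _log_inputs("cluster-expr", cfg, {"expression": Path(cfg.expression)})
    conditions = sorted(expr.metadata["condition"].unique())
    cond_a, cond_b = conditions[-1], conditions[0]  # untreated vs DOX when present
    if "untreated" in conditions and "DOX" in conditions:
        cond_a, cond_b = "untreated", "DOX"
    stages = list(dict.fromkeys(expr.metadata["stage"]))

    diff = expr_mod.diff_genes(expr, ("day1" if "day1" in stages else stages[0],
                                      cond_b, cond_a),
                               threshold_fold=cfg.diff_threshold_fold)
    log.info("cluster-expr: %d up, %d down at %.1f-fold",
             len(diff.up), len(diff.down), cfg.diff_threshold_fold)

    means = pd.DataFrame(
        {stage: expr.group_mean(stage, cond_a) for stage in stages}
    )
    km = expr_mod.kmeans_cluster(means, k=cfg.kmeans_k_bound, seed=cfg.seed)
    out = outdir / "expression_clusters.tsv"
    table = pd.DataFrame({"cluster": km.labels})
    table["diff"] = [
        "up" if g in diff.up else "down" if g in diff.down else "-"
        for g in table.index
    ]
    table.to_csv(out, sep="\t")
    log.info("cluster-expr: k = %d, inertia = %.1f", cfg.kmeans_k_bound,
             km.inertia)

    # finer clustering of the differential genes only (fold-change space)
    diff_gene_list = sorted(diff.up | diff.down)
    if diff_gene_list:
        fc = pd.DataFrame(
            {stage: expr.contrast_log2fc(stage, cond_b, cond_a)
             for stage in stages}
        ).loc[diff_gene_list]
        k_diff = min(cfg.kmeans_k_diff, len(diff_gene_list))
        km_diff = expr_mod.kmeans_cluster(fc, k=k_diff, seed=cfg.seed)
        pd.DataFrame({"cluster": km_diff.labels}).to_csv(
            outdir / "diff_gene_clusters.tsv", sep="\t")
        log.info("cluster-expr: %d differential genes in %d fold-change "
                 "clusters", len(diff_gene_list), k_diff)
    return out


def stage_report(cfg: AnalysisConfig, outdir: Path) -> Path:
    """Aggregate stage outputs; errors name the first missing artifact."""
    needed = {
        "classified peaks": outdir / "classified_peaks.tsv",
        "co-occurrence z matrix": outdir / "cooccurrence_z.tsv",
        "spacing histogram": outdir / "spacing_histogram.tsv",
        "expression clusters": outdir / "expression_clusters.tsv",
    }
    for what, p in needed.items():
        if not p.exists():
            raise MissingInputError(f"missing {what}: {p}")

    lines = ["# tfscape report", ""]
    table = pd.read_csv(needed["classified peaks"], sep="\t")
    counts = table["class"].value_counts().sort_index()
    lines.append("## Peak classes (1 lost / 2 shared / 3 gained)")
    for cls, n in counts.items():
        lines.append(f"class {cls}: {n} peaks ({100.0 * n / len(table):.1f}%)")
    lines.append("")

    z = pd.read_csv(needed["co-occurrence z matrix"], sep="\t", index_col=0)
    pairs = []
    for i, a in enumerate(z.index):
        for j, b in enumerate(z.columns):
            if j > i:
                pairs.append((float(z.iloc[i, j]), *sorted((a, b))))
    pairs.sort(reverse=True)
    lines.append("## Top co-occurring motif pairs (bootstrap z)")
    for zval, a, b in pairs[:5]:
        lines.append(f"{a} - {b}: z = {zval:.2f}")
    lines.append("")

    hist = pd.read_csv(needed["spacing histogram"], sep="\t")
    if hist["count"].sum() > 0:
        top = hist.loc[hist["count"].idxmax()]
        lines.append("## Composite spacing")
        lines.append(
            f"modal oriented distance = {int(top['distance'])} bp "
            f"({int(top['count'])} pairs, {cfg.spacing_anchor} convention)"
        )
    else:
        lines.append("## Composite spacing: no pairs in range")
    lines.append("")

    clusters = pd.read_csv(needed["expression clusters"], sep="\t", index_col=0)
    lines.append("## Expression clusters")
    for cl, n in clusters["cluster"].value_counts().sort_index().items():
        lines.append(f"cluster {cl}: {n} genes")
    n_diff = int((clusters["diff"] != "-").sum())
    lines.append(f"differential genes (>= {cfg.diff_threshold_fold:.0f}-fold): {n_diff}")
    lines.append("")

    out = outdir / "report.txt"
    out.write_text("\n".join(lines))
    log.info("report: written to %s", out)
    return out


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "annotate": stage_annotate,
    "scan": stage_scan,
    "cooccur": stage_cooccur,
    "spacing": stage_spacing,
    "cluster-expr": stage_cluster_expr,
    "report": stage_report,
}

ALL_ORDER = ["simulate", "classify", "annotate", "scan", "cooccur",
             "spacing", "cluster-expr", "report"]


def run_pipeline(cfg: AnalysisConfig, mode: str) -> Path:
    """Run one stage (or ``all``); returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    if log.getEffectiveLevel() > logging.INFO:
        log.setLevel(logging.INFO)
    try:
        log.info("run: mode=%s params=%s", mode,
                 json.dumps({k: v for k, v in cfg.to_dict().items()
                             if not isinstance(v, str) or v}))
        modes = ALL_ORDER if mode == "all" else [mode]
        for m in modes:
            if m not in STAGES:
                raise ValueError(f"unknown mode {m!r}")
            STAGES[m](cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
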