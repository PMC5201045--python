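"""Differential expression filtering, k-means clustering and per-class tests.

Expression values are log2-scale, genes x samples.  Replicates of a
(stage, condition) group are averaged before contrasts, so a contrast
log2 fold change is a difference of replicate-mean log2 values.  A gene
is called differential at a fold threshold f when |log2fc| >= log2(f)
(inclusive: "at least f-fold").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans


@dataclass
class ExpressionMatrix:
    """log2 expression (genes x samples) plus sample metadata.

    ``metadata`` is indexed by sample ID with columns ``stage``,
    ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_for(self, stage: str, condition: str) -> list[str]:
        md = self.metadata
        sel = md[(md["stage"] == stage) & (md["condition"] == condition)]
        return [s for s in sel.index if s in self.values.columns]

    def group_mean(self, stage: str, condition: str) -> pd.Series:
        cols = self.samples_for(stage, condition)
        if not cols:
            raise KeyError(f"no samples for stage={stage!r} condition={condition!r}")
        return self.values[cols].mean(axis=1)

    def contrast_log2fc(self, stage: str, cond_b: str, cond_a: str) -> pd.Series:
        """Replicate-mean log2fc of cond_b over cond_a at one stage."""
        return self.group_mean(stage, cond_b) - self.group_mean(stage, cond_a)

    @classmethod
    def from_tsv(cls, values_path: str | Path, metadata_path: str | Path
                 ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(values=values, metadata=metadata)

    def to_tsv(self, values_path: str | Path, metadata_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", float_format="%.5f")
        self.metadata.to_csv(metadata_path, sep="\t")


def fold_change_table(
    expr: ExpressionMatrix,
    contrasts: Mapping[str, tuple[str, str, str]],
) -> pd.DataFrame:
    """Genes x contrasts table of log2 fold changes.

    Each contrast is named and given as (stage, condition_b, condition_a);
    the column holds mean(cond_b) - mean(cond_a) per gene at that stage.
    """
    return pd.DataFrame(
        {name: expr.contrast_log2fc(*spec) for name, spec in contrasts.items()}
    )


@dataclass
class DiffResult:
    """Up/down gene sets for one contrast, with the underlying log2fc."""

    up: set[str]
    down: set[str]
    log2fc: pd.Series


def diff_genes(
    expr: ExpressionMatrix,
    contrast: tuple[str, str, str],
    threshold_fold: float = 2.0,
) -> DiffResult:
    """Genes changing at least ``threshold_fold``-fold in a contrast.

    ``contrast`` is (stage, condition_b, condition_a).  The threshold is
    inclusive on the log2 scale.
    """
    if threshold_fold <= 1:
        raise ValueError(f"threshold_fold must exceed 1, got {threshold_fold}")
    lfc = expr.contrast_log2fc(*contrast)
    t = np.log2(threshold_fold)
    return DiffResult(
        up=set(lfc.index[lfc >= t]),
        down=set(lfc.index[lfc <= -t]),
        log2fc=lfc,
    )


def diff_overlap_table(
    results: Mapping[str, DiffResult]
) -> pd.DataFrame:
    """Cross-contrast overlap of differential gene sets.

    Rows/columns are contrast names; cell (i, j) counts genes shared
    between contrast i's and contrast j's sets, reported separately for
    up ('up') and down ('down') via a two-level column index.  The
    diagonal holds each contrast's own set sizes.
    """
    names = list(results)
    cols = pd.MultiIndex.from_product([["up", "down"], names])
    table = pd.DataFrame(0, index=names, columns=cols, dtype=int)
    for i in names:
        for j in names:
            table.loc[i, ("up", j)] = len(results[i].up & results[j].up)
            table.loc[i, ("down", j)] = len(results[i].down & results[j].down)
    return table


@dataclass
class KMeansResult:
    labels: pd.Series  # gene -> cluster id (0-based)
    centroids: np.ndarray  # k x features
    inertia: float  # within-cluster sum of squares


def kmeans_cluster(
    values: pd.DataFrame,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    distance: str = "euclidean",
) -> KMeansResult:
    """Lloyd k-means on a genes x features matrix, best of ``n_restarts``
    random initialisations by within-cluster sum of squares.

    ``distance='correlation'`` row-standardises (mean 0, s.d. 1) before
    the Euclidean fit, equivalent to centered-correlation clustering up
    to a monotone transform of the distance.  Deterministic given seed.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(values):
        raise ValueError(f"k ({k}) exceeds gene count ({len(values)})")
    X = values.to_numpy(dtype=float)
    if distance == "correlation":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    elif distance != "euclidean":
        raise ValueError(f"unknown distance {distance!r}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(X)
    return KMeansResult(
        labels=pd.Series(labels, index=values.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


@dataclass
class ClassExpressionTest:
    """Per-peak-class expression summaries and rank-sum tests.

    ``summary`` has one row per class: n, median, q1, q3 of log2fc.
    ``pvalues`` maps class -> two-sided Wilcoxon rank-sum p of the class
    against the pooled remaining classes (exact when both group sizes
    are <= 12, normal approximation above).
    """

    summary: pd.DataFrame
    pvalues: dict[int, float]


def class_expression_test(
    gene_classes: Mapping[str, int],
    fc: pd.Series | pd.DataFrame,
    contrast: str | None = None,
    min_genes: int = 3,
) -> ClassExpressionTest:
    """Compare expression fold changes between peak classes.

    ``gene_classes`` maps gene -> class label; ``fc`` supplies each
    gene's log2 fold change (a Series, or a DataFrame with ``contrast``
    naming the column).  Classes with fewer than ``min_genes`` members
    are excluded with a warning.
    """
    if isinstance(fc, pd.DataFrame):
        if contrast is None:
            raise ValueError("contrast column name required with a DataFrame")
        fc = fc[contrast]
    by_class: dict[int, np.ndarray] = {}
    for cls in sorted(set(gene_classes.values())):
        genes = [g for g, c in gene_classes.items() if c == cls and g in fc.index]
        vals = fc.loc[genes].to_numpy(dtype=float)
        if len(vals) < min_genes:
            warnings.warn(
                f"class {cls} has {len(vals)} genes (< {min_genes}); excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        by_class[cls] = vals
    if len(by_class) < 2:
        raise ValueError("need >= 2 classes with enough genes")

    rows = []
    pvalues: dict[int, float] = {}
    for cls, vals in by_class.items():
        rest = np.concatenate([v for c, v in by_class.items() if c != cls])
        pvalues[cls] = rank_sum_test(vals, rest)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"class": cls, "n": len(vals), "median": med,
                     "q1": q1, "q3": q3, "p_vs_rest": pvalues[cls]})
    summary = pd.DataFrame(rows).set_index("class")
    return ClassExpressionTest(summary=summary, pvalues=pvalues)


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact null distribution when
    both samples have <= ``exact_max_n`` observations, normal
    approximation (with tie correction) otherwise."""
    method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the approximation
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
    return float(res.pvalue)
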