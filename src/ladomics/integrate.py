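"""Multi-omic integration around LADs.

Maps differential features (ATAC peaks, methylation clusters) onto genes,
intersects the resulting gene sets with differential expression, tests
whether gene sets sit closer to LADs than background (rank-sum on
nearest-LAD distances), correlates expression profiles across studies,
and ranks probes by absolute group difference for cross-disease
comparisons.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import AnnotationTrack, GenomicInterval, nearest_distance
from .tracksig import wilcoxon_rank_sum

__all__ = [
    "validate_gene_annotation",
    "assign_features_to_genes",
    "multiomic_overlap",
    "geneset_lad_distance_test",
    "expression_correlation",
    "top_differential_probes",
]


def validate_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Gene annotation contract: unique ids, valid body interval, TSS on
    the boundary or inside the body."""
    required = {"chrom", "start", "end", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns {sorted(missing)}")
    if genes.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("gene body end must exceed start")
    bad = (genes["tss"] < genes["start"]) | (genes["tss"] > genes["end"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} genes have TSS outside the body")
    return genes


def _gene_intervals(genes: pd.DataFrame, mode: str, promoter_window: int):
    if mode == "body":
        return genes["start"].to_numpy(), genes["end"].to_numpy()
    if mode == "promoter":
        tss = genes["tss"].to_numpy()
        return np.maximum(tss - promoter_window, 0), tss + promoter_window
    raise ValueError("mode must be 'body' or 'promoter'")


def assign_features_to_genes(
    features: AnnotationTrack,
    genes: pd.DataFrame,
    mode: str = "body",
    promoter_window: int = 2000,
) -> dict[str, set[str]]:
    """Map each feature to the set of genes it overlaps by >= 1 bp.

    ``mode='body'`` matches gene bodies (the default); ``mode='promoter'``
    matches TSS +/- ``promoter_window``.  Features overlapping no gene map
    to the empty set; a feature spanning several genes maps to all of
    them.  Keys are ``chrom:start-end`` (or the feature name if set).
    """
    genes = validate_gene_annotation(genes)
    starts, ends = _gene_intervals(genes, mode, promoter_window)
    chroms = genes["chrom"].to_numpy()
    ids = genes.index.to_numpy()
    out: dict[str, set[str]] = {}
    for iv in features:
        key = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        on = chroms == iv.chrom
        hit = on & (starts < iv.end) & (ends > iv.start)
        out[key] = set(ids[hit])
    return out


def multiomic_overlap(
    de_genes: set[str],
    accessible_genes: set[str],
    methylated_genes: set[str],
) -> dict[str, object]:
    """Venn structure of the three differential gene sets."""
    de, acc, met = set(de_genes), set(accessible_genes), set(methylated_genes)
    inter = {
        "de": de,
        "accessible": acc,
        "methylated": met,
        "de_and_accessible": de & acc,
        "de_and_methylated": de & met,
        "accessible_and_methylated": acc & met,
        "all_three": de & acc & met,
    }
    return {
        "counts": {k: len(v) for k, v in inter.items()},
        "members": {k: sorted(v) for k, v in inter.items()},
    }


def geneset_lad_distance_test(
    gene_sets: Mapping[str, Sequence[str]],
    genes: pd.DataFrame,
    lad_union: AnnotationTrack,
    use_tss: bool = False,
) -> dict[str, object]:
    """Nearest-LAD distance per gene set with pairwise rank-sum tests.

    Distances are measured from gene bodies (or TSS points with
    ``use_tss``) to the supplied LAD track (typically the union of lamin
    A and lamin B LADs); genes inside a LAD score 0.  Genes on
    chromosomes absent from the track have undefined distance and are
    excluded from medians and tests.
    """
    if len(lad_union) == 0:
        raise ValueError("empty LAD track")
    genes = validate_gene_annotation(genes)
    distances: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        members = list(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        missing = [g for g in members if g not in genes.index]
        if missing:
            raise ValueError(f"gene set {name!r}: unknown genes {missing[:5]}")
        sub = genes.loc[members]
        if use_tss:
            ivs = [
                GenomicInterval(c, int(t), int(t) + 1)
                for c, t in zip(sub["chrom"], sub["tss"])
            ]
        else:
            ivs = [
                GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(sub["chrom"], sub["start"], sub["end"])
            ]
        d = nearest_distance(ivs, lad_union)
        distances[name] = d[np.isfinite(d)]

    medians = {name: float(np.median(d)) for name, d in distances.items()}
    names = list(gene_sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            test = wilcoxon_rank_sum(distances[a], distances[b])
            pairwise[(a, b)] = test["p"]
    return {"distances": distances, "medians": medians, "pairwise_p": pairwise}


def expression_correlation(
    x: pd.Series, y: pd.Series, log_transform: bool = True
) -> dict[str, float]:
    """Pearson correlation of per-gene mean expression across studies.

    Genes are intersected by id; ``log_transform`` applies
    ``log2(value + 1)`` to both vectors first (conventional for
    FPKM-scale data).
    """
    shared = x.index.intersection(y.index)
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if xv.size < 3:
        raise ValueError("need >= 3 shared genes with finite values")
    if log_transform:
        if (xv < 0).any() or (yv < 0).any():
            raise ValueError("log transform requires non-negative expression")
        xv, yv = np.log2(xv + 1), np.log2(yv + 1)
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in an expression vector")
    r = float(stats.pearsonr(xv, yv).statistic)
    return {"pearson_r": r, "r_squared": r * r, "n_genes": int(xv.size)}


def top_differential_probes(
    mean_beta_a: pd.Series, mean_beta_b: pd.Series, k: int = 1000
) -> pd.DataFrame:
    """Top-k probes by absolute group mean difference, descending.

    Ties are broken by probe id so the ranking is deterministic.  Both
    series must share one probe universe (detection-filtered upstream).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not mean_beta_a.index.equals(mean_beta_b.index):
        raise ValueError("probe universes are misaligned")
    if k > mean_beta_a.size:
        warnings.warn(
            f"k={k} exceeds the {mean_beta_a.size}-probe universe", stacklevel=2
        )
    diff = (mean_beta_a - mean_beta_b).rename("difference")
    frame = pd.DataFrame(
        {"difference": diff, "abs_difference": diff.abs()}
    ).rename_axis("probe_id")
    frame = frame.sort_values(
        ["abs_difference", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return frame.head(k)
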