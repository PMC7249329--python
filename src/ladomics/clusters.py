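"""Bounded CpG probe clustering and selection of variable clusters.

Probes on each chromosome are grouped left-to-right into clusters bounded
by a maximum inter-probe gap (default 500 bp) and a maximum genomic span
(default 1500 bp, measured as last member position minus first member
position).  Every probe belongs to exactly one cluster; singletons are
allowed.  Cluster-level methylation is summarized per sample (mean by
default, median by flag) and clusters are ranked by the standard
deviation of the summary across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .diffmeth import BetaMatrix

__all__ = [
    "ProbeCluster",
    "bounded_cluster",
    "summarize_clusters",
    "top_variable_clusters",
    "BoundedProbeClusterer",
    "clusters_to_bed_frame",
]


@dataclass
class ProbeCluster:
    """A bounded group of nearby CpG probes on one chromosome."""

    cluster_id: str
    chrom: str
    start: int  # 0-based inclusive position of the first member probe
    end: int    # 0-based exclusive bound (last member position + 1)
    probe_ids: list[str]
    cluster_values: np.ndarray | None = None  # one summary value per sample
    variability: float | None = None

    @property
    def span(self) -> int:
        return self.end - 1 - self.start

    def __len__(self) -> int:
        return len(self.probe_ids)


def bounded_cluster(
    annot: pd.DataFrame, max_gap: int = 500, max_width: int = 1500
) -> list[ProbeCluster]:
    """Greedy left-to-right bounded clustering of probes.

    ``annot`` is indexed by probe id with ``chrom`` and 1-based ``pos``
    columns.  A new cluster opens when the gap to the previous probe
    exceeds ``max_gap`` or when adding the probe would stretch the span
    (last position - first position) beyond ``max_width``.
    """
    if annot[["chrom", "pos"]].duplicated().any():
        raise ValueError("duplicate (chrom, pos) probe coordinates")
    clusters: list[ProbeCluster] = []
    ordered = annot.sort_values(["chrom", "pos"], kind="mergesort")
    counter = 0
    for chrom, sub in ordered.groupby("chrom", sort=True):
        positions = sub["pos"].to_numpy(dtype=np.int64)
        ids = list(sub.index)
        members: list[int] = []
        for i in range(len(positions)):
            if members:
                gap = positions[i] - positions[members[-1]]
                span = positions[i] - positions[members[0]]
                if gap > max_gap or span > max_width:
                    counter += 1
                    clusters.append(_emit(counter, chrom, positions, ids, members))
                    members = []
            members.append(i)
        if members:
            counter += 1
            clusters.append(_emit(counter, chrom, positions, ids, members))
    return clusters


def _emit(counter, chrom, positions, ids, members) -> ProbeCluster:
    first, last = positions[members[0]], positions[members[-1]]
    return ProbeCluster(
        cluster_id=f"cl{counter:06d}",
        chrom=str(chrom),
        start=int(first) - 1,          # 1-based probe position -> half-open
        end=int(last),
        probe_ids=[ids[i] for i in members],
    )


def summarize_clusters(
    clusters: Sequence[ProbeCluster],
    beta: BetaMatrix,
    statistic: str = "mean",
) -> list[ProbeCluster]:
    """Attach per-sample cluster values and across-sample variability.

    The cluster value for a sample is the unweighted mean (or median)
    beta of the member probes; variability is the sample standard
    deviation (n-1 denominator) of those values across samples.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    values = beta.values
    out: list[ProbeCluster] = []
    for cl in clusters:
        present = [p for p in cl.probe_ids if p in values.index]
        if not present:
            raise ValueError(f"cluster {cl.cluster_id}: no member probe in matrix")
        block = values.loc[present].to_numpy()
        summary = np.mean(block, axis=0) if statistic == "mean" else np.median(block, axis=0)
        out.append(
            ProbeCluster(
                cl.cluster_id, cl.chrom, cl.start, cl.end, list(cl.probe_ids),
                cluster_values=summary,
                variability=float(np.std(summary, ddof=1)) if summary.size > 1 else 0.0,
            )
        )
    return out


def top_variable_clusters(
    clusters: Sequence[ProbeCluster], k: int = 5000
) -> list[ProbeCluster]:
    """Top-k clusters by variability, descending; ties broken by
    (chrom, start) so the ordering is stable across runs."""
    if any(cl.variability is None for cl in clusters):
        raise ValueError("variability not computed; run summarize_clusters first")
    if k > len(clusters):
        warnings.warn(
            f"requested k={k} but only {len(clusters)} clusters available",
            stacklevel=2,
        )
    ranked = sorted(clusters, key=lambda cl: (-cl.variability, cl.chrom, cl.start))
    return ranked[:k]


def clusters_to_bed_frame(clusters: Sequence[ProbeCluster]) -> pd.DataFrame:
    """BED-shaped frame (chrom, start, end, cluster_id, variability)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "cluster_id": [c.cluster_id for c in clusters],
            "variability": [c.variability for c in clusters],
        }
    )


class BoundedProbeClusterer(BaseEstimator, TransformerMixin):
    """Transformer from probe-level to cluster-level methylation.

    ``fit`` consumes the probe annotation (chrom/pos) and freezes the
    bounded clustering; ``transform`` maps a samples x probes matrix to
    samples x clusters summary values.  ``feature_names_in_`` order must
    match the annotation used at fit time.
    """

    def __init__(self, max_gap: int = 500, max_width: int = 1500,
                 statistic: str = "mean"):
        self.max_gap = max_gap
        self.max_width = max_width
        self.statistic = statistic

    def fit(self, annot: pd.DataFrame, y=None):
        self.clusters_ = bounded_cluster(annot, self.max_gap, self.max_width)
        self.probe_ids_ = list(annot.index)
        self._col = {p: i for i, p in enumerate(self.probe_ids_)}
        self._member_cols = [
            np.array([self._col[p] for p in cl.probe_ids], dtype=int)
            for cl in self.clusters_
        ]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.probe_ids_):
            raise ValueError("X columns must match the fitted probe annotation")
        fn = np.mean if self.statistic == "mean" else np.median
        return np.column_stack([fn(X[:, cols], axis=1) for cols in self._member_cols])
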