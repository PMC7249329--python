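"""Resampling consensus clustering of samples and PCA embedding.

Consensus clustering repeatedly subsamples the samples (and optionally
features), clusters each subsample by agglomerative hierarchical
clustering, and records for every sample pair the fraction of subsamples
containing both in which they landed in the same cluster.  Stability of
the consensus matrices across K = 2..max_k is summarised by the area
under the consensus CDF and the proportion of ambiguous clustering
(PAC); the selected K is the largest K that adds relative CDF area over
K-1 while keeping the consensus near-binary.

The inner clustering is average-linkage agglomeration on Euclidean
distances between samples; 1 - Pearson-correlation distance is available
via ``metric="correlation"``.  Euclidean is the default because
correlation distance degenerates under global compression of the beta
scale (a sample drifting toward partial methylation shrinks its feature
variance, inflating its correlation distance to its own subgroup beyond
its distance to other groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

__all__ = [
    "ConsensusResult",
    "ConsensusClustering",
    "consensus_cluster",
    "select_k",
    "pca_embed",
]


@dataclass
class ConsensusResult:
    """Consensus matrices, assignments and CDF areas for K = 2..max_k."""

    consensus: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    leaf_order: dict[int, np.ndarray]
    no_structure: bool = False


def _sample_distance(X: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance between rows (samples) of X."""
    if metric == "correlation":
        # 1 - Pearson correlation; constant rows get NaN -> replace by max
        d = pdist(X, metric="correlation")
        if np.any(~np.isfinite(d)):
            d = np.where(np.isfinite(d), d, 2.0)
        return d
    return pdist(X, metric=metric)


def _pac(mat: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    consensus entries falling strictly between ``lower`` and ``upper``."""
    iu = np.triu_indices(mat.shape[0], k=1)
    v = mat[iu]
    return float(np.mean((v > lower) & (v < upper))) if v.size else 0.0


def _cdf_area(mat: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.sort(mat[iu])
    if vals.size == 0:
        return 0.0
    # A = sum over consecutive sorted values of (x_i - x_{i-1}) * CDF(x_{i-1})
    xs = np.concatenate(([0.0], vals, [1.0]))
    cdf = np.searchsorted(vals, xs[:-1], side="right") / vals.size
    return float(np.sum(np.diff(xs) * cdf))


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Subsampled consensus clustering (sklearn-style clusterer).

    Parameters mirror the resampling scheme: ``reps`` subsamples of
    ``ceil(p_item * n)`` samples (and ``ceil(p_feature * m)`` features)
    drawn without replacement; each subsample is clustered by
    hierarchical agglomeration and cut at every K in ``2..max_k``.

    ``fit(X)`` with ``X`` of shape (n_samples, n_features) populates
    ``result_`` (:class:`ConsensusResult`), ``chosen_k_`` and ``labels_``
    (the assignment at the chosen K).  Fully reproducible from
    ``random_state``; per-rep generators are derived from the master seed
    by a counter so the rep loop could be parallelised without changing
    the stream.
    """

    def __init__(
        self,
        max_k: int = 6,
        reps: int = 1000,
        p_item: float = 0.8,
        p_feature: float = 1.0,
        linkage: str = "average",
        metric: str = "euclidean",
        delta_area_threshold: float = 0.05,
        pac_threshold: float = 0.01,
        random_state: int | None = None,
    ):
        self.max_k = max_k
        self.reps = reps
        self.p_item = p_item
        self.p_feature = p_feature
        self.linkage = linkage
        self.metric = metric
        self.delta_area_threshold = delta_area_threshold
        self.pac_threshold = pac_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        if n < self.max_k + 1:
            raise ValueError(f"need >= max_k + 1 = {self.max_k + 1} samples, got {n}")
        if np.any(~np.isfinite(X)):
            raise ValueError("X must not contain missing values")
        n_sub = int(np.ceil(self.p_item * n))
        if n_sub < self.max_k:
            raise ValueError("p_item * n_samples < max_k: subsamples cannot be cut")
        m_sub = int(np.ceil(self.p_feature * m))

        ks = range(2, self.max_k + 1)
        co_cluster = {k: np.zeros((n, n)) for k in ks}
        co_sample = np.zeros((n, n))
        seed = 0 if self.random_state is None else int(self.random_state)
        for rep in range(self.reps):
            rng = np.random.default_rng([seed, rep])
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            cols = (
                np.sort(rng.choice(m, size=m_sub, replace=False))
                if m_sub < m
                else slice(None)
            )
            sub = X[idx] if isinstance(cols, slice) else X[np.ix_(idx, cols)]
            d = _sample_distance(sub, self.metric)
            Z = hierarchy.linkage(d, method=self.linkage)
            co_sample[np.ix_(idx, idx)] += 1
            for k in ks:
                lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
                same = lab[:, None] == lab[None, :]
                co_cluster[k][np.ix_(idx, idx)] += same

        consensus: dict[int, np.ndarray] = {}
        assignments: dict[int, np.ndarray] = {}
        leaf_order: dict[int, np.ndarray] = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for k in ks:
                mat = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
                mat = 0.5 * (mat + mat.T)
                np.fill_diagonal(mat, 1.0)
                consensus[k] = mat
                dist = squareform(1.0 - mat, checks=False)
                Zf = hierarchy.linkage(dist, method=self.linkage)
                assignments[k] = hierarchy.fcluster(Zf, t=k, criterion="maxclust")
                leaf_order[k] = np.asarray(hierarchy.leaves_list(Zf))

        area = {k: _cdf_area(consensus[k]) for k in ks}
        pac = {k: _pac(consensus[k]) for k in ks}
        delta: dict[int, float] = {}
        for k in ks:
            if k == 2:
                delta[k] = area[k]
            else:
                prev = area[k - 1]
                delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0

        chosen, no_structure = _choose_k(
            delta, pac, self.delta_area_threshold, self.pac_threshold
        )
        if no_structure:
            warnings.warn("no consensus structure detected; chosen_k = 2", stacklevel=2)
        self.result_ = ConsensusResult(
            consensus=consensus,
            assignments=assignments,
            cdf_area=area,
            delta_area=delta,
            pac=pac,
            chosen_k=chosen,
            leaf_order=leaf_order,
            no_structure=no_structure,
        )
        self.chosen_k_ = chosen
        self.labels_ = assignments[chosen]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _choose_k(
    delta: dict[int, float],
    pac: dict[int, float],
    delta_threshold: float,
    pac_threshold: float,
) -> tuple[int, bool]:
    """Largest K that both adds consensus-CDF area over K-1 (relative
    delta above threshold) and remains crisp (PAC at or below threshold).

    The delta-area condition alone is insufficient: forcing a clean
    K-group structure into K+1 clusters splits a true cluster
    arbitrarily per subsample, which keeps adding a few percent of CDF
    area per extra K indefinitely.  Requiring near-binary consensus
    entries (low PAC) rejects those over-split solutions.  A flat,
    ambiguous K=2 consensus signals no structure at all.
    """
    candidates = [
        k for k in sorted(delta)
        if k > 2 and delta[k] > delta_threshold and pac[k] <= pac_threshold
    ]
    if candidates:
        return max(candidates), False
    return 2, pac.get(2, 0.0) > 0.1


def consensus_cluster(
    features: np.ndarray,
    max_k: int = 6,
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int | None = None,
    **kw,
) -> ConsensusResult:
    """Consensus clustering of a features x samples matrix.

    Functional wrapper over :class:`ConsensusClustering` (which follows
    the sklearn samples x features orientation).
    """
    est = ConsensusClustering(
        max_k=max_k, reps=reps, p_item=p_item, p_feature=p_feature,
        random_state=seed, **kw,
    )
    est.fit(np.asarray(features, dtype=float).T)
    return est.result_


def select_k(result: ConsensusResult) -> int:
    """The selected K under the relative delta-area criterion."""
    return result.chosen_k


def pca_embed(features: np.ndarray, n_components: int) -> dict[str, np.ndarray]:
    """PCA of samples over a features x samples matrix.

    Columns (samples) are embedded on the principal components of the
    column-centered data.  Component signs are fixed so that each
    component's largest-magnitude loading is positive, making the
    embedding reproducible across SVD implementations.

    Returns ``{"coordinates", "explained_variance_ratio", "loadings"}``
    with coordinates of shape (n_samples, n_components).
    """
    F = np.asarray(features, dtype=float)
    X = F.T  # samples x features
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(n_features, n_samples)")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance data cannot be embedded")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    return {
        "coordinates": coords * flip,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "loadings": loadings * flip[:, None],
    }
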