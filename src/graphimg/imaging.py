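"""Graph-to-image transform.

The d-dimensional node embedding of a graph is reduced to d_PCA
principal-component features per node (columns ordered by decreasing
explained variance), consecutive feature pairs (f1,f2), (f3,f4), ... are
taken as 2-D point clouds over the nodes, and each cloud is binned into
an r x r 2-D histogram.  Stacking the d_PCA/2 histograms gives a small
multi-channel count image representing the graph: each channel's pixel
values sum to |V| because every node falls into exactly one bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .embedding import EmbeddingMatrix

__all__ = [
    "NodeFeatureList",
    "FeaturePairMatrix",
    "GraphImage",
    "pca_features",
    "feature_pair",
    "histogram_channel",
    "graph_to_image",
]

logger = logging.getLogger(__name__)


@dataclass
class NodeFeatureList:
    """PCA-aligned node features: |V| x d_PCA, variance non-increasing by column."""

    node_ids: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.node_ids):
            raise ValueError("features must have one row per node")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    @property
    def d_pca(self) -> int:
        return self.features.shape[1]


@dataclass
class FeaturePairMatrix:
    """One pair of feature columns as a 2 x |V| matrix (pair c = features 2c-1, 2c)."""

    pair_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 2:
            raise ValueError("values must be a 2 x |V| matrix")
        if self.pair_index < 1:
            raise ValueError("pair_index must be >= 1")


@dataclass
class GraphImage:
    """r x r x n_channels integer count tensor; each channel sums to |V|."""

    channels: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ValueError("channels must be r x r x n_channels")
        if self.channels.shape[0] != self.resolution or self.channels.shape[1] != self.resolution:
            raise ValueError("channel shape does not match resolution")
        if np.any(self.channels < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[2]


def pca_features(emb: EmbeddingMatrix, d_pca: int) -> NodeFeatureList:
    """Scores of the embedding rows on the top d_pca principal components.

    A deterministic sign convention is applied: each component's loading
    vector is flipped so its largest-magnitude entry is positive, which
    removes the run-to-run sign ambiguity of eigenvectors.
    """
    d = emb.dim
    if not 2 <= d_pca < d:
        raise ValueError(f"need 2 <= d_pca < d (got d_pca={d_pca}, d={d})")
    if emb.vectors.shape[0] <= d_pca:
        raise ValueError("need more nodes than requested components")
    pca = PCA(n_components=d_pca, svd_solver="full")
    scores = pca.fit_transform(emb.vectors)
    for j in range(d_pca):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    return NodeFeatureList(list(emb.node_ids), scores)


def feature_pair(feats: NodeFeatureList, c: int) -> FeaturePairMatrix:
    """Features 2c-1 and 2c of every node, as the rows of a 2 x |V| matrix."""
    if c < 1 or 2 * c > feats.d_pca:
        raise ValueError(f"pair index {c} out of range for d_pca={feats.d_pca}")
    values = feats.features[:, [2 * c - 2, 2 * c - 1]].T
    return FeaturePairMatrix(c, values)


def _bin_indices(values: np.ndarray, r: int, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        logger.warning("zero-range feature: all nodes mapped to bin 0")
        return np.zeros(values.shape, dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * r).astype(np.int64)
    # maximum value belongs to the top bin (last bin closed)
    return np.clip(idx, 0, r - 1)


def histogram_channel(
    pairs: FeaturePairMatrix,
    r: int,
    edges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """r x r count matrix: cell (x, y) counts nodes binned there.

    Bins are r equal-width intervals spanning each feature's min-max
    range (half-open, last bin closed).  Feature 2c-1 indexes rows (x),
    feature 2c indexes columns (y).  ``edges`` overrides the per-graph
    range with dataset-global (lo, hi) per axis, for cross-subject
    comparability.
    """
    if r < 1:
        raise ValueError("resolution r must be >= 1")
    v = pairs.values
    if v.shape[1] < 1:
        raise ValueError("need at least one node")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite feature values")
    if edges is None:
        edges = ((v[0].min(), v[0].max()), (v[1].min(), v[1].max()))
    x = _bin_indices(v[0], r, *edges[0])
    y = _bin_indices(v[1], r, *edges[1])
    counts = np.zeros((r, r), dtype=np.int64)
    np.add.at(counts, (x, y), 1)
    return counts


def graph_to_image(emb: EmbeddingMatrix, d_pca: int = 4, r: int = 10) -> GraphImage:
    """Multi-channel histogram image of one graph (channel c from pair c)."""
    if d_pca % 2 != 0:
        raise ValueError("d_pca must be even (two features per image channel)")
    feats = pca_features(emb, d_pca)
    channels = [
        histogram_channel(feature_pair(feats, c), r) for c in range(1, d_pca // 2 + 1)
    ]
    return GraphImage(np.stack(channels, axis=-1), r)
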