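"""Node embeddings from random walks and skip-gram.

A corpus of first-order random walks is sampled on the weighted graph
(one walk rooted at every node, repeated for a number of iterations);
the walks are treated as sentences and a skip-gram model with full
softmax is trained on node co-occurrences within a window.  The input
weight matrix of the trained model is the |V| x d embedding table: rows
are nodes, and Euclidean/cosine proximity of rows reflects graph
neighbourhood structure.

On a dense PLI graph every node neighbours every other, so the walk
transition law matters: the default samples the successor with
probability proportional to edge weight, which is what lets community
structure shape the walks.  Uniform-over-neighbours sampling and top-k
edge sparsification are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_rng
from .connectivity import ConnectivityGraph

__all__ = [
    "WalkConfig",
    "SkipGramConfig",
    "SkipGramModel",
    "EmbeddingMatrix",
    "random_walk",
    "generate_walks",
    "train_skipgram",
    "node2vec",
]


@dataclass
class WalkConfig:
    """Walk sampling settings.

    iterations
        Number of passes over the node set; every node roots exactly one
        walk per pass, so ``iterations * |V|`` walks are produced.
    walk_length
        Number of nodes in each walk (the root included).
    transition
        ``"weighted"`` (successor probability proportional to edge
        weight, the default) or ``"uniform"`` (uniform over positive-
        weight neighbours).
    top_k
        If set, keep only each node's ``top_k`` strongest edges before
        walking (sparsification of dense graphs).
    """

    iterations: int = 10
    walk_length: int = 40
    seed: int = 0
    transition: str = "weighted"
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be a positive integer")
        if self.walk_length < 1:
            raise ValueError("walk_length must be a positive integer")
        if self.transition not in ("weighted", "uniform"):
            raise ValueError("transition must be 'weighted' or 'uniform'")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be a positive integer")


@dataclass
class SkipGramConfig:
    """Skip-gram training settings (window w, embedding size d)."""

    window: int = 5
    dim: int = 20
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    batch_size: int = 256
    negative: int = 0  # 0 = full softmax; >0 = that many negative samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.dim < 1 or self.epochs < 1:
            raise ValueError("window, dim and epochs must be positive integers")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be a positive integer")
        if self.negative < 0:
            raise ValueError("negative must be >= 0")


@dataclass
class SkipGramModel:
    """Shared-weight skip-gram: one |V| x d input and d x |V| output matrix.

    With one-hot inputs, a per-node three-layer network is exactly one
    row of ``input_weights`` plus the shared ``output_weights``; the
    hidden activation of node i is ``input_weights[i]``.
    """

    input_weights: np.ndarray
    output_weights: np.ndarray

    def __post_init__(self) -> None:
        if self.input_weights.shape[1] != self.output_weights.shape[0]:
            raise ValueError("inconsistent hidden dimension")
        if not (
            np.all(np.isfinite(self.input_weights))
            and np.all(np.isfinite(self.output_weights))
        ):
            raise ValueError("model weights contain non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.input_weights.shape[0]

    def predict_context(self, node: int) -> np.ndarray:
        """Softmax co-occurrence distribution over all nodes for one focus node."""
        scores = self.input_weights[node] @ self.output_weights
        scores = scores - scores.max()
        p = np.exp(scores)
        return p / p.sum()


@dataclass
class EmbeddingMatrix:
    """|V| x d node-embedding table; row order follows the graph's node order."""

    node_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("vectors must have one row per node id")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class _TransitionTable:
    """Per-node cumulative successor probabilities for O(log V) sampling."""

    def __init__(self, graph: ConnectivityGraph, transition: str = "weighted",
                 top_k: int | None = None):
        w = np.array(graph.weights, dtype=float)
        np.fill_diagonal(w, 0.0)  # self-loops never followed
        if top_k is not None and top_k < w.shape[0] - 1:
            pruned = np.zeros_like(w)
            for i in range(w.shape[0]):
                keep = np.argsort(w[i])[-top_k:]
                pruned[i, keep] = w[i, keep]
            w = pruned
        if transition == "uniform":
            w = (w > 0).astype(float)
        self.isolated = np.where(w.sum(axis=1) == 0)[0]
        row_sums = w.sum(axis=1)
        safe = np.where(row_sums > 0, row_sums, 1.0)
        self.cum = np.cumsum(w / safe[:, None], axis=1)
        self.node_ids = graph.node_ids

    def step(self, node: int, rng: np.random.Generator) -> int:
        if node in self.isolated:
            raise ValueError(
                f"node {self.node_ids[node]!r} has no positive-weight neighbour"
            )
        return int(np.searchsorted(self.cum[node], rng.random(), side="right"))


def _walk_from(table: _TransitionTable, start: int, length: int,
               rng: np.random.Generator) -> np.ndarray:
    walk = np.empty(length, dtype=np.int64)
    walk[0] = start
    for i in range(1, length):
        walk[i] = table.step(walk[i - 1], rng)
    return walk


def random_walk(graph: ConnectivityGraph, start: int, length: int,
                rng: np.random.Generator, transition: str = "weighted") -> np.ndarray:
    """One random walk of ``length`` nodes rooted at ``start``.

    Each step samples the successor among positive-weight neighbours of
    the current node, with probability proportional to edge weight (or
    uniformly when ``transition="uniform"``).
    """
    if not 0 <= start < graph.n_nodes:
        raise ValueError(f"start index {start} out of range")
    table = _TransitionTable(graph, transition=transition)
    if length > 1 and start in table.isolated:
        raise ValueError(f"node {graph.node_ids[start]!r} has no positive-weight neighbour")
    return _walk_from(table, start, length, rng)


def generate_walks(graph: ConnectivityGraph, cfg: WalkConfig) -> list[np.ndarray]:
    """The walk corpus: ``iterations`` passes, one walk rooted at every node."""
    table = _TransitionTable(graph, transition=cfg.transition, top_k=cfg.top_k)
    if cfg.walk_length > 1 and table.isolated.size:
        bad = [graph.node_ids[i] for i in table.isolated]
        raise ValueError(f"nodes without positive-weight neighbours: {bad}")
    rng = derive_rng(cfg.seed, "walks")
    walks = []
    for _ in range(cfg.iterations):
        for start in range(graph.n_nodes):
            walks.append(_walk_from(table, start, cfg.walk_length, rng))
    return walks


def _context_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (focus, context) pairs with |offset| <= window, clipped at walk ends."""
    focus_parts, ctx_parts = [], []
    for walk in walks:
        n = len(walk)
        for off in range(1, window + 1):
            if off >= n:
                break
            focus_parts.append(walk[:-off])
            ctx_parts.append(walk[off:])
            focus_parts.append(walk[off:])
            ctx_parts.append(walk[:-off])
    if not focus_parts:
        raise ValueError("walks too short to form any context pair")
    return np.concatenate(focus_parts), np.concatenate(ctx_parts)


def train_skipgram(
    walks: list[np.ndarray],
    cfg: SkipGramConfig,
    n_nodes: int,
    init_input: np.ndarray | None = None,
    init_output: np.ndarray | None = None,
) -> SkipGramModel:
    """Train skip-gram on the walk corpus by minibatch SGD.

    Full softmax over the node vocabulary by default (the vocabulary is
    a few hundred sensors); ``cfg.negative > 0`` switches to negative
    sampling with uniform negatives for large graphs.  The learning rate
    decays linearly from ``learning_rate`` to ``min_learning_rate``.
    """
    if not walks:
        raise ValueError("empty walk list")
    for w in walks:
        if np.any(w >= n_nodes) or np.any(w < 0):
            raise ValueError("walk contains a node index outside [0, n_nodes)")
    rng = derive_rng(cfg.seed, "skipgram")
    d = cfg.dim
    if init_input is None:
        w_in = rng.uniform(-0.5 / d, 0.5 / d, size=(n_nodes, d))
    else:
        w_in = np.array(init_input, dtype=float, copy=True)
    if init_output is None:
        w_out = rng.uniform(-0.5 / d, 0.5 / d, size=(d, n_nodes))
    else:
        w_out = np.array(init_output, dtype=float, copy=True)

    focus, ctx = _context_pairs(walks, cfg.window)
    n_pairs = focus.size
    n_batches_total = cfg.epochs * int(np.ceil(n_pairs / cfg.batch_size))
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            f, c = focus[sel], ctx[sel]
            frac = batch_no / max(n_batches_total - 1, 1)
            lr = max(cfg.learning_rate * (1 - frac), cfg.min_learning_rate)
            if cfg.negative == 0:
                _softmax_update(w_in, w_out, f, c, lr)
            else:
                neg = rng.integers(0, n_nodes, size=(f.size, cfg.negative))
                _negative_update(w_in, w_out, f, c, neg, lr)
            batch_no += 1
    return SkipGramModel(w_in, w_out)


# Updates are summed over the minibatch (not averaged): each pair then
# contributes a full SGD step at the current learning rate, matching
# per-pair word2vec semantics up to within-batch parameter staleness.

def _softmax_update(w_in, w_out, f, c, lr) -> None:
    h = w_in[f]                            # (B, d)
    scores = h @ w_out                     # (B, V)
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)
    p[np.arange(f.size), c] -= 1.0         # d(loss)/d(scores)
    grad_h = p @ w_out.T
    w_out -= lr * (h.T @ p)
    np.add.at(w_in, f, -lr * grad_h)


def _negative_update(w_in, w_out, f, c, neg, lr) -> None:
    h = w_in[f]                                        # (B, d)
    targets = np.concatenate([c[:, None], neg], axis=1)  # (B, 1+k)
    labels = np.zeros(targets.shape)
    labels[:, 0] = 1.0
    v = w_out.T[targets]                               # (B, 1+k, d)
    scores = np.einsum("bd,bkd->bk", h, v)
    sig = 1.0 / (1.0 + np.exp(-scores))
    err = sig - labels                                 # (B, 1+k)
    grad_h = np.einsum("bk,bkd->bd", err, v)
    grad_v = err[:, :, None] * h[:, None, :]
    np.add.at(w_out.T, targets.ravel(),
              -lr * grad_v.reshape(-1, h.shape[1]))
    np.add.at(w_in, f, -lr * grad_h)


def node2vec(graph: ConnectivityGraph, walk_cfg: WalkConfig,
             sg_cfg: SkipGramConfig) -> EmbeddingMatrix:
    """Full embedding pipeline: walk corpus then skip-gram; returns Phi (|V| x d)."""
    if graph.n_nodes < 2:
        raise ValueError("graph must have at least 2 nodes")
    if sg_cfg.dim >= graph.n_nodes:
        raise ValueError(
            f"embedding dim {sg_cfg.dim} must be much smaller than |V|={graph.n_nodes}"
        )
    walks = generate_walks(graph, walk_cfg)
    model = train_skipgram(walks, sg_cfg, graph.n_nodes)
    return EmbeddingMatrix(list(graph.node_ids), model.input_weights)
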