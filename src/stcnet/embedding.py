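"""Second-order biased random walks and skip-gram embedding of the network.

The walk bias follows the node2vec scheme: from the step ``prev -> curr`` the
unnormalized weight of moving to out-neighbor ``x`` of ``curr`` is ``1/p`` if
``x == prev`` (return), ``1`` if ``x`` is an out-neighbor of ``prev`` (common
neighbor) and ``1/q`` otherwise (outward).  Adjacency is taken over directed
out-edges, the consistent reading for a directed graph.

Because drug and STC nodes have in-degree 0, walks that start on them step
into the protein subgraph and never come back; their vectors are therefore
trained entirely from protein context.  That is the intended construction,
not an artifact: it places compounds and STCs in the same protein-defined
embedding space.

Skip-gram training with negative sampling is implemented in-package as a
numba-compiled sequential SGD loop following the classic word2vec
conventions (dynamic window, unigram^0.75 noise distribution, linearly
decaying learning rate).  Single-threaded training under a fixed seed is
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .network import HeteroNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    """Random-walk hyperparameters.

    ``p`` (return) and ``q`` (in-out) control the second-order bias;
    ``num_walks`` walks of up to ``walk_length`` nodes start from every node.
    """

    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    seed: int = 0

    def validate(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("walk bias parameters p and q must be > 0")
        if self.num_walks < 1 or self.walk_length < 1:
            raise ValueError("num_walks and walk_length must be >= 1")


@dataclass(frozen=True)
class EmbeddingParams:
    """Skip-gram hyperparameters (word2vec conventions)."""

    dimensions: int = 128
    window: int = 10
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 0.0001
    seed: int = 0

    def validate(self) -> None:
        for name in ("dimensions", "window", "epochs", "negative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class EmbeddingMatrix:
    """Ordered node ids plus their d-dimensional vectors (one row each)."""

    node_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.node_ids) != self.vectors.shape[0]:
            raise ValueError("node_ids and vectors disagree in length")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    @property
    def dimensions(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def subset(self, nodes: Sequence[str]) -> np.ndarray:
        """Row matrix for ``nodes``; raises KeyError naming a missing node."""
        rows = []
        for n in nodes:
            if n not in self._index:
                raise KeyError(f"no embedding for node {n!r}")
            rows.append(self._index[n])
        return self.vectors[np.array(rows, dtype=int)]

    def save(self, path: str | Path) -> None:
        """Persist in word2vec text format (``N d`` header, then rows)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.node_ids)} {self.dimensions}\n")
            for n, row in zip(self.node_ids, self.vectors):
                fh.write(n + " " + " ".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        with open(path, encoding="utf-8") as fh:
            n, d = map(int, fh.readline().split())
            ids, rows = [], np.empty((n, d))
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                ids.append(parts[0])
                rows[i] = [float(x) for x in parts[1:]]
        return cls(ids, rows)


def transition_distribution(net: HeteroNetwork, prev: str, curr: str,
                            params: WalkParams) -> dict[str, float]:
    """Second-order step distribution over out-neighbors of ``curr``.

    Requires ``(prev, curr)`` to be an edge and ``curr`` to have at least one
    out-edge (always true on a valid integrated network, where only protein
    nodes can be interior walk positions and proteins keep their symmetric
    PPI edges).
    """
    params.validate()
    if not net.has_edge(prev, curr):
        raise ValueError(f"({prev!r}, {curr!r}) is not an edge of the network")
    succ = net.out_neighbors(curr)
    if not succ:
        raise ValueError(f"node {curr!r} has no out-edges")
    prev_out = set(net.out_neighbors(prev))
    weights = {}
    for x in succ:
        if x == prev:
            weights[x] = 1.0 / params.p
        elif x in prev_out:
            weights[x] = 1.0
        else:
            weights[x] = 1.0 / params.q
    total = sum(weights.values())
    return {x: w / total for x, w in weights.items()}


@njit(cache=True)
def _contains_sorted(arr, lo, hi, x):
    while lo < hi:
        mid = (lo + hi) // 2
        v = arr[mid]
        if v == x:
            return True
        if v < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def _walk_kernel(starts, indptr, indices, p, q, walk_length, seed):
    np.random.seed(seed)
    n_walks = starts.shape[0]
    walks = np.full((n_walks, walk_length), -1, dtype=np.int64)
    inv_p = 1.0 / p
    inv_q = 1.0 / q
    for w in range(n_walks):
        cur = starts[w]
        walks[w, 0] = cur
        deg = indptr[cur + 1] - indptr[cur]
        if deg == 0 or walk_length == 1:
            continue
        # first step: uniform over out-neighbors
        nxt = indices[indptr[cur] + np.random.randint(deg)]
        walks[w, 1] = nxt
        prev = cur
        cur = nxt
        for t in range(2, walk_length):
            base = indptr[cur]
            deg = indptr[cur + 1] - base
            if deg == 0:
                break
            total = 0.0
            weights = np.empty(deg)
            plo, phi = indptr[prev], indptr[prev + 1]
            for j in range(deg):
                x = indices[base + j]
                if x == prev:
                    wgt = inv_p
                elif _contains_sorted(indices, plo, phi, x):
                    wgt = 1.0
                else:
                    wgt = inv_q
                weights[j] = wgt
                total += wgt
            r = np.random.random() * total
            acc = 0.0
            pick = deg - 1
            for j in range(deg):
                acc += weights[j]
                if r < acc:
                    pick = j
                    break
            nxt = indices[base + pick]
            walks[w, t] = nxt
            prev = cur
            cur = nxt
    return walks


def generate_walks(net: HeteroNetwork, params: WalkParams) -> list[list[str]]:
    """Sample the walk corpus: ``num_walks`` walks started from every node.

    Start-node order is reshuffled on every pass; the first step from a start
    node is uniform over its out-neighbors and subsequent steps follow
    :func:`transition_distribution`.  Walks stop early at nodes without
    out-edges (cannot happen after the first step on a valid network).
    Fully reproducible from ``params.seed``.
    """
    params.validate()
    node_ids, _, indptr, indices = net.indexed()
    rng = np.random.default_rng(params.seed)
    n = len(node_ids)
    starts = np.concatenate(
        [rng.permutation(n) for _ in range(params.num_walks)])
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    raw = _walk_kernel(starts.astype(np.int64), indptr, indices,
                       float(params.p), float(params.q),
                       int(params.walk_length), kernel_seed)
    walks = []
    for row in raw:
        walk = [node_ids[i] for i in row[row >= 0]]
        walks.append(walk)
    return walks


@njit(cache=True)
def _sgns_kernel(corpus, offsets, epoch_orders, win, wout, window, negative,
                 noise_cdf, alpha0, min_alpha, seed):
    np.random.seed(seed)
    dim = win.shape[1]
    n_vocab = noise_cdf.shape[0]
    epochs = epoch_orders.shape[0]
    total_tokens = corpus.shape[0] * epochs
    processed = 0
    for e in range(epochs):
        for oi in range(epoch_orders.shape[1]):
            wk = epoch_orders[e, oi]
            start = offsets[wk]
            end = offsets[wk + 1]
            for i in range(start, end):
                alpha = alpha0 - (alpha0 - min_alpha) * processed / total_tokens
                processed += 1
                center = corpus[i]
                b = 1 + np.random.randint(window)
                lo = i - b
                if lo < start:
                    lo = start
                hi = i + b + 1
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = corpus[j]
                    neu1e = np.zeros(dim)
                    for k in range(negative + 1):
                        if k == 0:
                            target = ctx
                            label = 1.0
                        else:
                            r = np.random.random()
                            # binary search on the noise CDF
                            t_lo, t_hi = 0, n_vocab - 1
                            while t_lo < t_hi:
                                mid = (t_lo + t_hi) // 2
                                if noise_cdf[mid] < r:
                                    t_lo = mid + 1
                                else:
                                    t_hi = mid
                            target = t_lo
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for dd in range(dim):
                            f += win[center, dd] * wout[target, dd]
                        if f > 8.0:
                            s = 1.0
                        elif f < -8.0:
                            s = 0.0
                        else:
                            s = 1.0 / (1.0 + np.exp(-f))
                        g = (label - s) * alpha
                        for dd in range(dim):
                            neu1e[dd] += g * wout[target, dd]
                            wout[target, dd] += g * win[center, dd]
                    for dd in range(dim):
                        win[center, dd] += neu1e[dd]


def train_embeddings(walks: Sequence[Sequence[str]],
                     params: EmbeddingParams) -> EmbeddingMatrix:
    """Train skip-gram-with-negative-sampling vectors on a walk corpus.

    The vocabulary is every node appearing in the corpus (sorted order);
    noise distribution is the unigram frequency raised to 3/4.  Training is
    sequential SGD with a per-token dynamic window (uniform on 1..window) and
    a learning rate decaying linearly from ``alpha`` to ``min_alpha``.
    Deterministic under a fixed seed.
    """
    params.validate()
    walks = [w for w in walks if len(w) > 0]
    if not walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({node for walk in walks for node in walk})
    index = {n: i for i, n in enumerate(vocab)}

    offsets = np.zeros(len(walks) + 1, dtype=np.int64)
    for i, w in enumerate(walks):
        offsets[i + 1] = offsets[i] + len(w)
    corpus = np.empty(offsets[-1], dtype=np.int64)
    for i, w in enumerate(walks):
        corpus[offsets[i]:offsets[i + 1]] = [index[n] for n in w]

    counts = np.bincount(corpus, minlength=len(vocab)).astype(np.float64)
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    rng = np.random.default_rng(params.seed)
    dim = params.dimensions
    win = (rng.random((len(vocab), dim)) - 0.5) / dim
    wout = np.zeros((len(vocab), dim))
    epoch_orders = np.stack(
        [rng.permutation(len(walks)) for _ in range(params.epochs)]
    ).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    _sgns_kernel(corpus, offsets, epoch_orders, win, wout,
                 int(params.window), int(params.negative), noise_cdf,
                 float(params.alpha), float(params.min_alpha), kernel_seed)
    return EmbeddingMatrix(vocab, win)


def save_walks(walks: Sequence[Sequence[str]], path: str | Path) -> None:
    """One walk per line, space-separated node ids."""
    with open(path, "w", encoding="utf-8") as fh:
        for w in walks:
            fh.write(" ".join(w) + "\n")


def load_walks(path: str | Path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.split() for line in fh if line.strip()]


class Node2VecEmbedding(BaseEstimator):
    """Network-to-vector estimator: biased walks plus skip-gram training.

    Scikit-learn-style estimator whose :meth:`fit` takes a
    :class:`~stcnet.network.HeteroNetwork` instead of a sample matrix.

    Parameters
    ----------
    p, q : float
        Second-order walk bias (return / in-out); 1.0 each is the unbiased
        walk.
    num_walks, walk_length : int
        Walks started per node and nodes per walk.
    dimensions, window, epochs, negative : int
        Skip-gram settings, defaulting to the common node2vec benchmark
        values (d=128, window 10, 5 epochs, 5 negative samples).
    seed : int
        Drives both walk sampling and SGD; a fixed seed gives bit-identical
        embeddings.

    Attributes
    ----------
    embedding_ : EmbeddingMatrix
        Vectors for every node that appeared in at least one walk.
    n_walks_ : int
        Number of walks in the trained corpus.
    """

    def __init__(self, p: float = 1.0, q: float = 1.0, num_walks: int = 10,
                 walk_length: int = 80, dimensions: int = 128,
                 window: int = 10, epochs: int = 5, negative: int = 5,
                 seed: int = 0):
        self.p = p
        self.q = q
        self.num_walks = num_walks
        self.walk_length = walk_length
        self.dimensions = dimensions
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.seed = seed

    def walk_params(self) -> WalkParams:
        return WalkParams(p=self.p, q=self.q, num_walks=self.num_walks,
                          walk_length=self.walk_length, seed=self.seed)

    def embedding_params(self) -> EmbeddingParams:
        return EmbeddingParams(dimensions=self.dimensions, window=self.window,
                               epochs=self.epochs, negative=self.negative,
                               seed=self.seed)

    def fit(self, network: HeteroNetwork, y=None) -> "Node2VecEmbedding":
        walks = generate_walks(network, self.walk_params())
        self.embedding_ = train_embeddings(walks, self.embedding_params())
        self.n_walks_ = len(walks)
        return self

    def transform(self, nodes: Sequence[str]) -> np.ndarray:
        """Vectors for ``nodes`` from the fitted embedding."""
        if not hasattr(self, "embedding_"):
            raise RuntimeError("Node2VecEmbedding is not fitted")
        return self.embedding_.subset(nodes)
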