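"""Node embeddings: uniform random walks + skip-gram with negative sampling.

The largest component of the knowledge graph is turned into a corpus of
first-order (uniform) random walks — every node starts ``walks_per_node``
walks of ``walk_length`` steps, each step moving to a uniformly random
neighbor of the undirected view.  The corpus is then fed to a word2vec-style
skip-gram model trained with negative sampling (negatives drawn from the
unigram distribution raised to the 3/4 power), logistic loss, and SGD with
linear learning-rate decay.  Training is single-threaded and fully seeded,
so a fixed seed reproduces the embedding bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .kg_build import KnowledgeGraph


class EmbeddingConfigError(ValueError):
    pass


@dataclass
class EmbeddingParams:
    dimension: int = 32
    walks_per_node: int = 10
    walk_length: int = 40
    #: small window concentrates co-occurrence on shared-respondent paths,
    #: the association signal on an (almost) bipartite person-term graph
    window: int = 2
    negatives_per_positive: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.dimension < 2:
            raise EmbeddingConfigError("embedding dimension must be >= 2")
        if self.walk_length < 2:
            raise EmbeddingConfigError("walk_length must be >= 2")
        if self.window < 1:
            raise EmbeddingConfigError("window must be >= 1")


@dataclass
class WalkCorpus:
    node_ids: list                  # position -> node id
    walks: np.ndarray               # (n_walks, walk_length) int32 positions


@dataclass
class EmbeddingMatrix:
    ids: list
    vectors: np.ndarray             # (n_nodes, dimension) float32
    params: EmbeddingParams | None = None
    losses: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {nid: i for i, nid in enumerate(self.ids)}
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite entries")

    def __contains__(self, node_id) -> bool:
        return node_id in self._index

    def vector(self, node_id) -> np.ndarray:
        try:
            return self.vectors[self._index[node_id]]
        except KeyError:
            raise KeyError(f"node {node_id!r} not present in embedding") from None

    def save(self, path, sidecar_path=None) -> None:
        path = Path(path)
        dim = self.vectors.shape[1]
        header = "node_id\t" + "\t".join(f"d{i}" for i in range(dim))
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for nid, row in zip(self.ids, self.vectors):
                fh.write(nid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        if sidecar_path is None:
            sidecar_path = path.with_suffix(".json")
        meta = asdict(self.params) if self.params else {}
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "EmbeddingMatrix":
        ids, rows = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(ids=ids, vectors=np.asarray(rows, dtype=np.float32))


# ---------------------------------------------------------------------------
# walks


def _adjacency_csr(graph: KnowledgeGraph) -> tuple[list, np.ndarray, np.ndarray]:
    """Sorted-node CSR adjacency of the undirected view."""
    node_ids = sorted(graph.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    neighbors: list[set] = [set() for _ in node_ids]
    for pair in graph.undirected_pairs():
        u, v = sorted(pair)
        neighbors[index[u]].add(index[v])
        neighbors[index[v]].add(index[u])
    degrees = np.array([len(s) for s in neighbors], dtype=np.int64)
    indptr = np.zeros(len(node_ids) + 1, dtype=np.int64)
    np.cumsum(degrees, out=indptr[1:])
    indices = np.empty(int(indptr[-1]), dtype=np.int32)
    for i, s in enumerate(neighbors):
        indices[indptr[i]:indptr[i + 1]] = sorted(s)
    return node_ids, indptr, indices


def generate_walks(graph: KnowledgeGraph, params: EmbeddingParams) -> WalkCorpus:
    """Uniform random-walk corpus over the (connected) input graph."""
    params.validate()
    node_ids, indptr, indices = _adjacency_csr(graph)
    degrees = np.diff(indptr)
    if graph.n_nodes >= 2 and (degrees == 0).any():
        bad = [node_ids[i] for i in np.flatnonzero(degrees == 0)[:5]]
        raise RuntimeError(
            f"walk generation requires a connected graph; isolated nodes: {bad}"
        )
    rng = np.random.default_rng(params.seed)
    n = len(node_ids)
    n_walks = n * params.walks_per_node
    walks = np.empty((n_walks, params.walk_length), dtype=np.int32)
    walks[:, 0] = np.repeat(np.arange(n, dtype=np.int32), params.walks_per_node)
    for step in range(1, params.walk_length):
        cur = walks[:, step - 1]
        deg = degrees[cur]
        offsets = rng.integers(0, deg)
        walks[:, step] = indices[indptr[cur] + offsets]
    return WalkCorpus(node_ids=node_ids, walks=walks)


def single_walk(graph: KnowledgeGraph, start, length: int, seed: int = 0) -> list:
    """One long uniform walk, for stationarity diagnostics."""
    node_ids, indptr, indices = _adjacency_csr(graph)
    index = {nid: i for i, nid in enumerate(node_ids)}
    rng = np.random.default_rng(seed)
    pos = index[start]
    out = [pos]
    for _ in range(length - 1):
        lo, hi = indptr[pos], indptr[pos + 1]
        if hi == lo:
            raise RuntimeError(f"walk stranded at isolated node {node_ids[pos]}")
        pos = int(indices[lo + rng.integers(hi - lo)])
        out.append(pos)
    return [node_ids[p] for p in out]


# ---------------------------------------------------------------------------
# skip-gram with negative sampling


_SIG_TABLE_SIZE = 2048
_SIG_MAX = 8.0
_SIG_TABLE = (1.0 / (1.0 + np.exp(
    -(np.arange(_SIG_TABLE_SIZE) / _SIG_TABLE_SIZE * 2 - 1) * _SIG_MAX
))).astype(np.float32)
_NEGLOG_TABLE = (-np.log(np.clip(_SIG_TABLE, 1e-10, None))).astype(np.float32)


def _alias_table(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vose alias tables for O(1) sampling from a discrete distribution."""
    n = len(probs)
    prob = np.zeros(n, dtype=np.float32)
    alias = np.zeros(n, dtype=np.int32)
    scaled = probs * n / probs.sum()
    small = [i for i in range(n) if scaled[i] < 1.0]
    large = [i for i in range(n) if scaled[i] >= 1.0]
    scaled = scaled.copy()
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] + scaled[s] - 1.0
        (small if scaled[l] < 1.0 else large).append(l)
    for i in small + large:
        prob[i] = 1.0
    return prob, alias


@njit(nogil=True, fastmath=True)
def _sgns_kernel(walks, window, negatives, lr0, epochs, neg_prob, neg_alias,
                 W, C, seed, losses, sig_table, neglog_table):
    n_walks, length = walks.shape
    dim = W.shape[1]
    vocab = neg_prob.shape[0]
    table_size = sig_table.shape[0]
    state = np.uint64(seed * 2 + 1)

    # expected positive pairs (dynamic window averages (window+1)/2 each side)
    total = float(epochs) * n_walks * length * (window + 1.0)
    lr_min = lr0 * 1e-4

    neu1e = np.zeros(dim, dtype=np.float32)
    processed = 0.0
    for ep in range(epochs):
        loss_sum = 0.0
        loss_n = 0
        for s in range(n_walks):
            for t in range(length):
                center = walks[s, t]
                # dynamic window shrink, as in canonical word2vec
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                b = 1 + int(
                    (state * np.uint64(2685821657736338717)) >> np.uint64(33)
                ) % window
                lo = t - b
                if lo < 0:
                    lo = 0
                hi = t + b
                if hi > length - 1:
                    hi = length - 1
                lr = lr0 * (1.0 - processed / total)
                if lr < lr_min:
                    lr = lr_min
                glr = np.float32(lr)
                for j in range(lo, hi + 1):
                    if j == t:
                        continue
                    processed += 1.0
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for k in range(negatives + 1):
                        if k == 0:
                            target = walks[s, j]
                            label = np.float32(1.0)
                        else:
                            # xorshift64* then alias lookup (unigram^0.75)
                            state ^= state >> np.uint64(12)
                            state ^= state << np.uint64(25)
                            state ^= state >> np.uint64(27)
                            r = np.float64(
                                (state * np.uint64(2685821657736338717))
                                >> np.uint64(11)
                            ) / 9007199254740992.0
                            x = r * vocab
                            cell = int(x)
                            if cell >= vocab:
                                cell = vocab - 1
                            if x - cell < neg_prob[cell]:
                                target = cell
                            else:
                                target = neg_alias[cell]
                            if target == center:
                                continue
                            label = np.float32(0.0)
                        dot = np.float32(0.0)
                        for d in range(dim):
                            dot += W[center, d] * C[target, d]
                        # table lookup for sigmoid and -log(sigmoid)
                        x = dot if label == 1.0 else -dot
                        if x >= 8.0:
                            sig_x = np.float32(1.0)
                            nll = np.float32(0.0)
                        elif x <= -8.0:
                            sig_x = np.float32(0.0)
                            nll = np.float32(23.0)
                        else:
                            ti = int((x / 8.0 + 1.0) * 0.5 * table_size)
                            if ti >= table_size:
                                ti = table_size - 1
                            sig_x = sig_table[ti]
                            nll = neglog_table[ti]
                        sig = sig_x if label == 1.0 else np.float32(1.0) - sig_x
                        loss_sum += nll
                        loss_n += 1
                        g = (label - sig) * glr
                        for d in range(dim):
                            neu1e[d] += g * C[target, d]
                            C[target, d] += g * W[center, d]
                    for d in range(dim):
                        W[center, d] += neu1e[d]
        losses[ep] = loss_sum / max(loss_n, 1)


def train_skipgram(corpus: WalkCorpus, params: EmbeddingParams) -> EmbeddingMatrix:
    """Train skip-gram/negative-sampling embeddings over a walk corpus.

    ``epochs=0`` returns the seeded random initialization untouched (center
    vectors uniform in ±0.5/dimension, context vectors zero).  With a fixed
    seed the result is reproducible exactly: one thread, one RNG stream.
    """
    params.validate()
    if corpus.walks.size == 0:
        raise ValueError("walk corpus is empty")
    n = len(corpus.node_ids)
    dim = params.dimension
    rng = np.random.default_rng(params.seed)
    W = ((rng.random((n, dim)) - 0.5) / dim).astype(np.float32)
    C = np.zeros((n, dim), dtype=np.float32)

    counts = np.bincount(corpus.walks.ravel(), minlength=n).astype(np.float64)
    neg_prob, neg_alias = _alias_table(counts ** 0.75)

    losses = np.zeros(max(params.epochs, 1), dtype=np.float64)
    if params.epochs > 0:
        _sgns_kernel(
            corpus.walks, params.window, params.negatives_per_positive,
            params.learning_rate, params.epochs, neg_prob, neg_alias, W, C,
            params.seed + 1, losses, _SIG_TABLE, _NEGLOG_TABLE,
        )
    return EmbeddingMatrix(
        ids=list(corpus.node_ids), vectors=W, params=params,
        losses=losses[: params.epochs],
    )


def embed_graph(graph: KnowledgeGraph, params: EmbeddingParams) -> EmbeddingMatrix:
    """Walks + skip-gram in one call."""
    return train_skipgram(generate_walks(graph, params), params)


# ---------------------------------------------------------------------------
# edge-embedding operators

EDGE_OPERATORS = ("hadamard", "average", "L1", "L2")


def _combine(x: np.ndarray, y: np.ndarray, operator: str) -> np.ndarray:
    if operator == "hadamard":
        return x * y
    if operator == "average":
        return (x + y) / 2.0
    if operator == "L1":
        return np.abs(x - y)
    if operator == "L2":
        return (x - y) ** 2
    raise ValueError(f"unknown edge operator {operator!r}; choose from {EDGE_OPERATORS}")


def _unit(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return x / np.maximum(norms, 1e-12)


def embed_edge(u, v, emb: EmbeddingMatrix, operator: str = "hadamard",
               normalize: bool = False) -> np.ndarray:
    """Symmetric element-wise combination of two node vectors.

    With ``normalize`` vectors are L2-normalized first, so edge features
    encode directional alignment only; by default raw vectors are combined,
    keeping the magnitude information the downstream classifier can use.
    """
    x, y = emb.vector(u), emb.vector(v)
    if normalize:
        x, y = _unit(x), _unit(y)
    return _combine(x, y, operator)


def edge_feature_matrix(pairs, emb: EmbeddingMatrix, operator: str = "hadamard",
                        normalize: bool = False) -> np.ndarray:
    """Stacked edge features for a sequence of (u, v) pairs."""
    idx = emb._index
    ui = np.fromiter((idx[u] for u, _ in pairs), dtype=np.int64, count=len(pairs))
    vi = np.fromiter((idx[v] for _, v in pairs), dtype=np.int64, count=len(pairs))
    x, y = emb.vectors[ui], emb.vectors[vi]
    if normalize:
        x, y = _unit(x), _unit(y)
    return _combine(x, y, operator)
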