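"""Edge holdout, random-forest edge classification, and link prediction.

The holdout mirrors the connectivity-preserving scheme used for knowledge
graph embedding evaluation: test edges are drawn only from edges whose
simultaneous removal cannot split a component.  Operationally, a random
spanning forest (built from a seeded shuffle of the edge list) is pinned to
the training set; any subset of the remaining edges can then be held out
without changing the component count, and the achieved test fraction is
capped at (E − V + #components) / E on sparse graphs.

Classification follows the embedding arm of the study design: a random
forest (501 trees, maximum depth 15) over element-wise edge embeddings of
held-in positives and uniformly sampled non-edges, evaluated by AUROC on
the held-out edges, then retrained on the full graph to score candidate
links whose source is a disorder of interest; predictions with score above
the configured threshold (default 0.8) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .embedding import EmbeddingMatrix, edge_feature_matrix
from .kg_build import KnowledgeGraph


@dataclass
class EdgeSplit:
    train_edges: set        # {frozenset((u, v))}
    test_edges: set
    target_test_fraction: float
    achieved_test_fraction: float

    @property
    def all_edges(self) -> set:
        return self.train_edges | self.test_edges


@dataclass
class ClassifierParams:
    n_trees: int = 501
    max_depth: int = 15
    seed: int = 0
    negatives_per_positive: float = 1.0
    score_threshold: float = 0.8
    edge_operator: str = "hadamard"
    #: "uniform": negatives drawn uniformly over all node pairs (the default
    #: of standard graph-embedding toolkits); "type_matched": negatives
    #: mirror the person/term pair-type mix of the positives, removing the
    #: node-type shortcut on person-heavy graphs
    negative_sampling: str = "uniform"
    #: per-tree bootstrap subsample fraction (subagging); None = full bootstrap
    max_samples: float | None = 0.5

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.score_threshold < 1.0 and self.score_threshold not in (0.0, 1.0):
            raise ValueError("score_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class LinkPrediction:
    source: str
    destination: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"prediction score outside [0,1]: {self.score}")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def split_edges(graph: KnowledgeGraph, fraction: float = 0.3, seed: int = 0) -> EdgeSplit:
    """Connectivity-preserving train/test edge split.

    A seeded shuffle of the undirected edge list feeds a union-find pass; the
    first edges to connect their endpoints form a random spanning forest and
    stay in training, so removing any subset of the remaining edges leaves
    the component count unchanged.  Test edges are then the first
    ``fraction``·E removable edges of the shuffle.  On a tree every edge is
    a bridge and the achieved fraction is 0 (warned, not raised).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("test fraction must lie in [0, 1)")
    edges = sorted(tuple(sorted(p)) for p in graph.undirected_pairs())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    uf = _UnionFind(graph.nodes)
    forest, removable = [], []
    for i in order:
        u, v = edges[i]
        if uf.union(u, v):
            forest.append(edges[i])
        else:
            removable.append(edges[i])
    n_test = min(round(fraction * len(edges)), len(removable))
    test = {frozenset(e) for e in removable[:n_test]}
    train = {frozenset(e) for e in edges} - test
    achieved = len(test) / len(edges) if edges else 0.0
    if n_test < round(fraction * len(edges)):
        warnings.warn(
            f"only {achieved:.3f} of edges removable without splitting a "
            f"component (target {fraction:.3f})", stacklevel=2,
        )
    return EdgeSplit(train, test, fraction, achieved)


def sample_negative_edges(graph: KnowledgeGraph, n: int, seed: int = 0) -> set:
    """n uniformly sampled non-edges (no self-pairs, no duplicates)."""
    nodes = sorted(graph.nodes)
    return _sample_non_edges(nodes, graph.undirected_pairs(), n,
                             np.random.default_rng(seed))


def _sample_non_edges(nodes, forbidden: set, n: int, rng) -> set:
    v = len(nodes)
    possible = v * (v - 1) // 2 - len({f for f in forbidden if len(f) == 2})
    if n > possible:
        raise ValueError(f"requested {n} negative edges but only {possible} non-edges exist")
    out: set = set()
    # rejection sampling, falling back to enumeration on dense graphs
    max_tries = 50 * max(n, 1) + 1000
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        i, j = rng.integers(v), rng.integers(v)
        if i == j:
            continue
        pair = frozenset((nodes[i], nodes[j]))
        if pair in forbidden or pair in out:
            continue
        out.add(pair)
    if len(out) < n:
        all_pairs = [frozenset((nodes[i], nodes[j]))
                     for i in range(v) for j in range(i + 1, v)]
        rest = [p for p in all_pairs if p not in forbidden and p not in out]
        idx = rng.choice(len(rest), size=n - len(out), replace=False)
        out.update(rest[i] for i in idx)
    return out


def _pairs(edge_set) -> list:
    return [tuple(sorted(e)) for e in sorted(edge_set, key=lambda e: tuple(sorted(e)))]


def _looks_like_term(node_id: str) -> bool:
    # ontology terms are CURIEs (PREFIX:LOCALID); person ids carry no colon
    return ":" in node_id


def _sample_matched_negatives(pos_pairs, nodes, forbidden: set, ratio: float, rng) -> list:
    """Non-edges mirroring the person/term pair-type composition of positives.

    On survey knowledge graphs most nodes are persons while positives are
    person–term and term–term pairs; uniform non-edge sampling would let the
    classifier solve the task by node-type detection alone.  Sampling
    negatives within each pair type removes that shortcut.
    """
    terms = [x for x in nodes if _looks_like_term(x)]
    persons = [x for x in nodes if not _looks_like_term(x)]
    n_tt = sum(1 for u, v in pos_pairs if _looks_like_term(u) and _looks_like_term(v))
    n_pt = len(pos_pairs) - n_tt
    out: set = set()

    def _draw(pool_a, pool_b, n_target) -> None:
        tries = 0
        while len(out) < n_target and tries < 200 * (n_target + 10):
            tries += 1
            u = pool_a[int(rng.integers(len(pool_a)))]
            v = pool_b[int(rng.integers(len(pool_b)))]
            if u == v:
                continue
            pair = frozenset((u, v))
            if pair in forbidden or pair in out:
                continue
            out.add(pair)

    if persons and terms:
        _draw(persons, terms, int(round(ratio * n_pt)))
    want = len(out) + int(round(ratio * n_tt))
    if len(terms) >= 2:
        _draw(terms, terms, want)
    return _pairs(out)


@dataclass
class EdgeClassifier:
    model: RandomForestClassifier
    operator: str

    def scores(self, pairs, emb: EmbeddingMatrix) -> np.ndarray:
        if not len(pairs):
            return np.zeros(0)
        X = edge_feature_matrix(list(pairs), emb, self.operator)
        return self.model.predict_proba(X)[:, 1]


def _fit_forest(pos_pairs, neg_pairs, emb, params: ClassifierParams) -> EdgeClassifier:
    X = np.vstack([
        edge_feature_matrix(pos_pairs, emb, params.edge_operator),
        edge_feature_matrix(neg_pairs, emb, params.edge_operator),
    ])
    y = np.r_[np.ones(len(pos_pairs), dtype=int), np.zeros(len(neg_pairs), dtype=int)]
    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        max_samples=params.max_samples,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return EdgeClassifier(model, params.edge_operator)


def train_edge_classifier(
    split: EdgeSplit, emb: EmbeddingMatrix, params: ClassifierParams
) -> EdgeClassifier:
    """Fit the random forest on train positives plus sampled non-edges.

    Negatives are drawn uniformly among node pairs of the embedding,
    rejecting every edge of the full graph (train and test), at the
    configured negatives-per-positive ratio (1:1 by default).
    """
    params.validate()
    pos = _pairs(split.train_edges)
    if not pos:
        raise ValueError("empty training edge set")
    rng = np.random.default_rng(params.seed)
    neg = _negatives_for(pos, sorted(emb.ids), split.all_edges,
                         params.negatives_per_positive, rng,
                         params.negative_sampling)
    return _fit_forest(pos, neg, emb, params)


def _negatives_for(pos_pairs, nodes, forbidden, ratio, rng, mode) -> list:
    if mode == "type_matched":
        return _sample_matched_negatives(pos_pairs, nodes, forbidden, ratio, rng)
    if mode == "degree":
        n = int(round(ratio * len(pos_pairs)))
        return _sample_scale_free_negatives(pos_pairs, nodes, forbidden, n, rng)
    if mode == "uniform":
        n = int(round(ratio * len(pos_pairs)))
        return _pairs(_sample_non_edges(nodes, forbidden, n, rng))
    raise ValueError(f"unknown negative sampling mode {mode!r}")


def _sample_scale_free_negatives(pos_pairs, nodes, forbidden: set, n: int, rng) -> list:
    """Non-edges with endpoints drawn proportionally to node degree.

    Matching the degree distribution of the positives (scale-free negative
    sampling, the default of standard graph-embedding toolkits) prevents the
    classifier from treating sheer popularity as edge evidence.
    """
    index = {x: i for i, x in enumerate(nodes)}
    deg = np.zeros(len(nodes), dtype=np.float64)
    for u, v in pos_pairs:
        deg[index[u]] += 1
        deg[index[v]] += 1
    deg = np.maximum(deg, 1e-12)
    cum = np.cumsum(deg / deg.sum())
    out: set = set()
    tries = 0
    while len(out) < n and tries < 200 * (n + 10):
        tries += 1
        i, j = np.searchsorted(cum, rng.random(2))
        if i == j:
            continue
        pair = frozenset((nodes[int(i)], nodes[int(j)]))
        if pair in forbidden or pair in out:
            continue
        out.add(pair)
    return _pairs(out)


def auroc_scores(pos_scores, neg_scores) -> float:
    """AUROC by the Mann–Whitney rank statistic; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC needs scores from both classes")
    ranks = rankdata(np.r_[pos, neg])
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def evaluate_auroc(
    model: EdgeClassifier, split: EdgeSplit, emb: EmbeddingMatrix, seed: int = 0,
    negative_sampling: str = "uniform",
) -> float:
    """AUROC of held-out positives vs freshly sampled non-edges."""
    pos = _pairs(split.test_edges)
    if not pos:
        raise ValueError("empty test edge set")
    rng = np.random.default_rng(seed)
    neg = _negatives_for(pos, sorted(emb.ids), split.all_edges, 1.0, rng,
                         negative_sampling)
    return auroc_scores(model.scores(pos, emb), model.scores(neg, emb))


def train_full_classifier(
    graph: KnowledgeGraph, emb: EmbeddingMatrix, params: ClassifierParams
) -> EdgeClassifier:
    """Retrain on every edge of the (full, no-holdout) graph."""
    params.validate()
    pos = _pairs(graph.undirected_pairs())
    rng = np.random.default_rng(params.seed)
    neg = _negatives_for(pos, sorted(emb.ids), graph.undirected_pairs(),
                         params.negatives_per_positive, rng,
                         params.negative_sampling)
    return _fit_forest(pos, neg, emb, params)


def predict_frd_links(
    graph: KnowledgeGraph,
    emb: EmbeddingMatrix,
    params: ClassifierParams,
    frd_nodes,
    model: EdgeClassifier | None = None,
) -> list:
    """Score every (disorder, candidate) pair and keep those above threshold.

    Candidates are all non-person ontology-term nodes except the disorder
    itself.  Results are sorted by descending score, ties broken by
    destination id.  Disorders absent from the graph are skipped with a
    warning.  A pre-trained full-graph ``model`` may be passed to avoid
    refitting.
    """
    params.validate()
    if model is None:
        model = train_full_classifier(graph, emb, params)
    candidates = [t for t in graph.term_ids() if t in emb]
    out: list[LinkPrediction] = []
    for frd in frd_nodes:
        if frd not in graph.nodes or frd not in emb:
            warnings.warn(f"disorder node {frd} absent from the largest component; "
                          "skipped", stacklevel=2)
            continue
        pairs = [(frd, c) for c in candidates if c != frd]
        scores = model.scores(pairs, emb)
        for (src, dst), sc in zip(pairs, scores):
            if sc > params.score_threshold:
                out.append(LinkPrediction(src, dst, float(sc)))
    out.sort(key=lambda p: (-p.score, p.destination))
    return out
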