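"""Shared fixtures: hand-built micro-ontologies and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from kglink.kg_build import KnowledgeGraph
from kglink.ontology import Ontology, Term
from kglink.synthetic_data import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def med_ontology() -> Ontology:
    """Tiny chemical hierarchy including lansoprazole with a brand synonym."""
    onto = Ontology()
    onto.add(Term("CHEBI:0000001", "chemical root", "chemical"))
    onto.add(Term("CHEBI:6375", "Lansoprazole", "chemical",
                  parents=("CHEBI:0000001",), synonyms=("Prevacid",)))
    onto.add(Term("CHEBI:7772", "omeprazole", "chemical",
                  parents=("CHEBI:0000001",)))
    onto.add(Term("HP:0000001", "phenotype root", "phenotype"))
    onto.add(Term("HP:0000138", "Ovarian cyst", "phenotype",
                  parents=("HP:0000001",)))
    onto.add(Term("FOODON:0000001", "food root", "food"))
    onto.add(Term("FOODON:03301", "carrot", "food", parents=("FOODON:0000001",)))
    # two distinct terms sharing a label, to force a lexical tie
    onto.add(Term("CHEBI:9999001", "ambiguol", "chemical",
                  parents=("CHEBI:0000001",)))
    onto.add(Term("CHEBI:9999002", "Ambiguol", "chemical",
                  parents=("CHEBI:0000001",)))
    return onto


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-drawer bundle: quick to generate, still exercises every path."""
    return SyntheticConfig(
        n_respondents=300,
        n_ontology_terms={b: 12 for b in
                          ("disease", "phenotype", "food", "chemical",
                           "exposure", "medical_action")},
        n_questions={"health": 8, "internal": 6, "external": 4},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


def make_graph(edges, categories=None) -> KnowledgeGraph:
    """Build a KnowledgeGraph from (subject, predicate, object) triples."""
    kg = KnowledgeGraph()
    categories = categories or {}
    nodes = {x for s, _, o in edges for x in (s, o)}
    for n in sorted(nodes):
        kg.add_node(n, categories.get(n, "other"), n)
    for s, p, o in edges:
        kg.add_edge(s, p, o)
    return kg


@pytest.fixture
def triangle() -> KnowledgeGraph:
    return make_graph([("a", "r", "b"), ("b", "r", "c"), ("a", "r", "c")])


@pytest.fixture
def path_graph() -> KnowledgeGraph:
    return make_graph([("a", "r", "b"), ("b", "r", "c")])


def two_clique_graph(k: int = 10) -> KnowledgeGraph:
    """Two k-cliques joined by a single bridge edge."""
    edges = []
    left = [f"L{i:02d}" for i in range(k)]
    right = [f"R{i:02d}" for i in range(k)]
    for group in (left, right):
        for i in range(k):
            for j in range(i + 1, k):
                edges.append((group[i], "r", group[j]))
    edges.append((left[0], "bridge", right[0]))
    return make_graph(edges)


def union_find_components(nodes, pairs) -> list:
    """Independent union-find oracle for connected components."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in pairs:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(groups.values(), key=len, reverse=True)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
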