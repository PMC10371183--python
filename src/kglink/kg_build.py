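"""Heterogeneous knowledge-graph assembly and component analysis.

Person assertions, the full merged ontology (including terms never touched
by any survey answer), and supplemental food→chemical / food→nutrient link
tables are combined into one multigraph-free knowledge graph: nodes are
persons or ontology terms, edges are typed (subject, predicate, object)
triples with duplicates collapsed.  Edges are stored directed but all
connectivity is computed on the undirected view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .ontology import Ontology

PERSON_CATEGORY = "person"


@dataclass(frozen=True)
class Node:
    id: str
    category: str
    label: str


@dataclass
class KnowledgeGraph:
    nodes: dict = field(default_factory=dict)   # id -> Node
    edges: set = field(default_factory=set)     # {(subject, predicate, object)}

    def add_node(self, node_id: str, category: str, label: str = "") -> None:
        if node_id not in self.nodes:
            self.nodes[node_id] = Node(node_id, category, label)

    def add_edge(self, subject: str, predicate: str, obj: str) -> None:
        if subject == obj:
            raise ValueError(f"self-loop rejected: {subject} -{predicate}-> {obj}")
        if subject not in self.nodes or obj not in self.nodes:
            raise ValueError(f"edge endpoint missing from node set: ({subject}, {obj})")
        if (self.nodes[subject].category == PERSON_CATEGORY
                and self.nodes[obj].category == PERSON_CATEGORY):
            raise ValueError("person→person edges are not allowed")
        self.edges.add((subject, predicate, obj))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def person_ids(self) -> list:
        return sorted(i for i, nd in self.nodes.items()
                      if nd.category == PERSON_CATEGORY)

    def term_ids(self) -> list:
        return sorted(i for i, nd in self.nodes.items()
                      if nd.category != PERSON_CATEGORY)

    def undirected_pairs(self) -> set:
        """Unordered endpoint pairs, predicates and duplicates dropped."""
        return {frozenset((s, o)) for s, _, o in self.edges}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((s, o) for s, _, o in self.edges)
        return g

    def __eq__(self, other) -> bool:
        return (isinstance(other, KnowledgeGraph)
                and self.nodes == other.nodes and self.edges == other.edges)


@dataclass
class ComponentSummary:
    n_components: int
    component_sizes: list           # sorted descending
    largest_size: int
    removed_persons: int
    removed_fraction: float


class BuildError(ValueError):
    pass


def build_graph(
    assertions,
    ontology: Ontology,
    supplemental=(),
    respondent_ids=None,
    question_curies=None,
) -> KnowledgeGraph:
    """Merge assertions, the full ontology, and supplemental links.

    ``respondent_ids`` optionally names the full respondent population;
    respondents with no positive mapped answer then appear as isolated
    person nodes (they are the ones later dropped with the small
    components).  ``question_curies`` restricts supplemental food links to
    foods actually reachable from some survey question, mirroring the rule
    that external crop/nutrient data without a matching question is left
    out.  Duplicate identical triples collapse to one edge.
    """
    kg = KnowledgeGraph()
    for term in sorted(ontology.terms.values(), key=lambda t: t.curie):
        kg.add_node(term.curie, term.branch, term.label)
    for child, parent in ontology.is_a_edges():
        kg.add_edge(child, "subclass_of", parent)

    if respondent_ids is None:
        respondent_ids = sorted({a.respondent_id for a in assertions})
    for rid in respondent_ids:
        kg.add_node(rid, PERSON_CATEGORY, rid)

    for a in assertions:
        if a.object_curie not in ontology:
            raise BuildError(
                f"assertion references unknown CURIE {a.object_curie} "
                f"(respondent {a.respondent_id})"
            )
        if a.respondent_id not in kg.nodes:
            kg.add_node(a.respondent_id, PERSON_CATEGORY, a.respondent_id)
        kg.add_edge(a.respondent_id, a.predicate, a.object_curie)

    for subject, predicate, obj in supplemental:
        if subject not in ontology or obj not in ontology:
            raise BuildError(f"supplemental link references unknown CURIE: "
                             f"({subject}, {predicate}, {obj})")
        if question_curies is not None and subject not in question_curies:
            continue
        kg.add_edge(subject, predicate, obj)
    return kg


def connected_components(graph: KnowledgeGraph) -> ComponentSummary:
    """Component census on the undirected view of the graph."""
    if graph.n_nodes == 0:
        raise BuildError("cannot analyze components of an empty graph")
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    sizes = sorted((len(c) for c in comps), reverse=True)
    largest = _largest_component(comps)
    persons = set(graph.person_ids())
    removed = len(persons - largest)
    frac = removed / len(persons) if persons else 0.0
    return ComponentSummary(
        n_components=len(comps),
        component_sizes=sizes,
        largest_size=len(largest),
        removed_persons=removed,
        removed_fraction=frac,
    )


def _largest_component(comps) -> set:
    # ties broken by the lexicographically smallest member node id
    return sorted(comps, key=lambda c: (-len(c), min(c)))[0]


def extract_largest_component(graph: KnowledgeGraph) -> KnowledgeGraph:
    """Induced subgraph on the largest connected component.

    Size ties go to the component containing the lexicographically smallest
    node id.  Every edge whose endpoints both survive is kept.
    """
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    keep = _largest_component(comps)
    sub = KnowledgeGraph()
    for nid in sorted(keep):
        nd = graph.nodes[nid]
        sub.add_node(nd.id, nd.category, nd.label)
    for s, p, o in graph.edges:
        if s in keep and o in keep:
            sub.edges.add((s, p, o))
    return sub


# ---------------------------------------------------------------------------
# KGX-dialect TSV i/o


def write_kgx(graph: KnowledgeGraph, node_path, edge_path) -> None:
    nodes = pd.DataFrame(
        [{"id": nd.id, "category": nd.category, "name": nd.label}
         for nd in sorted(graph.nodes.values(), key=lambda nd: nd.id)],
        columns=["id", "category", "name"],
    )
    edges = pd.DataFrame(
        sorted(graph.edges), columns=["subject", "predicate", "object"]
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)


class KGXParseError(ValueError):
    pass


def _read_tsv(path, columns) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise KGXParseError(f"{path}: missing columns {missing}")
    return frame

def read_kgx(node_path, edge_path) -> KnowledgeGraph:
    """Round-trip counterpart of :func:`write_kgx`."""
    nodes = _read_tsv(node_path, ["id", "category", "name"])
    edges = _read_tsv(edge_path, ["subject", "predicate", "object"])
    kg = KnowledgeGraph()
    for lineno, row in enumerate(nodes.itertuples(index=False), start=2):
        if not row.id:
            raise KGXParseError(f"{node_path}: empty node id at line {lineno}")
        kg.add_node(row.id, row.category, row.name)
    for lineno, row in enumerate(edges.itertuples(index=False), start=2):
        try:
            kg.add_edge(row.subject, row.predicate, row.object)
        except ValueError as err:
            raise KGXParseError(f"{edge_path}: line {lineno}: {err}") from err
    return kg


def write_component_summary(summary: ComponentSummary, path) -> None:
    import json

    Path(path).write_text(json.dumps({
        "n_components": summary.n_components,
        "largest_size": summary.largest_size,
        "removed_persons": summary.removed_persons,
        "removed_fraction": summary.removed_fraction,
        "component_sizes_head": summary.component_sizes[:20],
    }, indent=2))
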