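"""Minimal ontology container: CURIE-identified terms in per-branch is_a DAGs.

Terms carry a label, optional exact synonyms, and zero or more ``is_a``
parents.  Branches correspond to the major biomedical vocabularies the
pipeline harmonizes against (diseases, phenotypes, foods, chemicals,
environmental exposures, medical actions); each branch is rooted so that
every term's ancestor closure terminates at a single branch root.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: branch name -> CURIE prefix used for synthetic term ids
BRANCH_PREFIXES = {
    "disease": "MONDO",
    "phenotype": "HP",
    "food": "FOODON",
    "chemical": "CHEBI",
    "exposure": "ECTO",
    "medical_action": "MAXO",
}

BRANCHES = tuple(BRANCH_PREFIXES)

_CURIE_RE = re.compile(r"^[A-Za-z][\w.]*:\S+$")
_PUNCT_RE = re.compile(r"[^\w\s]")


def is_curie(value: str) -> bool:
    """True if ``value`` is a well-formed ``PREFIX:LOCALID`` identifier."""
    return bool(_CURIE_RE.match(value))


def normalize_label(text: str) -> str:
    """Case-fold, strip punctuation, and collapse whitespace for lexical matching."""
    text = _PUNCT_RE.sub(" ", text.casefold())
    return " ".join(text.split())


@dataclass(frozen=True)
class Term:
    curie: str
    label: str
    branch: str
    parents: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()


@dataclass
class Ontology:
    """A set of terms forming rooted DAGs, one per branch."""

    terms: dict[str, Term] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._label_index: dict[str, list[str]] | None = None
        self._synonym_index: dict[str, list[str]] | None = None

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def add(self, term: Term) -> None:
        if term.curie in self.terms:
            raise ValueError(f"duplicate CURIE {term.curie}")
        self.terms[term.curie] = term
        self._label_index = None
        self._synonym_index = None

    def resolve(self, curie: str) -> Term:
        try:
            return self.terms[curie]
        except KeyError:
            raise KeyError(f"CURIE {curie} not present in ontology") from None

    def roots(self) -> list[str]:
        return [t.curie for t in self.terms.values() if not t.parents]

    def branch_terms(self, branch: str) -> list[str]:
        return [t.curie for t in self.terms.values() if t.branch == branch]

    def ancestors(self, curie: str) -> set[str]:
        """All is_a ancestors of ``curie`` (excluding itself)."""
        seen: set[str] = set()
        stack = list(self.resolve(curie).parents)
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self.resolve(cur).parents)
        return seen

    def is_a_edges(self) -> list[tuple[str, str]]:
        """All (child, parent) pairs, in deterministic order."""
        return [
            (t.curie, p)
            for t in sorted(self.terms.values(), key=lambda t: t.curie)
            for p in t.parents
        ]

    # -- lexical lookup ------------------------------------------------

    def _build_indexes(self) -> None:
        labels: dict[str, list[str]] = {}
        syns: dict[str, list[str]] = {}
        for term in self.terms.values():
            labels.setdefault(normalize_label(term.label), []).append(term.curie)
            for s in term.synonyms:
                syns.setdefault(normalize_label(s), []).append(term.curie)
        self._label_index = labels
        self._synonym_index = syns

    def label_matches(self, text: str) -> list[str]:
        if self._label_index is None:
            self._build_indexes()
        return sorted(self._label_index.get(normalize_label(text), []))

    def synonym_matches(self, text: str) -> list[str]:
        if self._synonym_index is None:
            self._build_indexes()
        return sorted(self._synonym_index.get(normalize_label(text), []))

    # -- KGX-style serialization ---------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node and edge tables in the KGX dialect (id,category,name / s,p,o)."""
        nodes = pd.DataFrame(
            [
                {"id": t.curie, "category": t.branch, "name": t.label,
                 "synonyms": "|".join(t.synonyms)}
                for t in sorted(self.terms.values(), key=lambda t: t.curie)
            ]
        )
        edges = pd.DataFrame(
            [{"subject": c, "predicate": "subclass_of", "object": p}
             for c, p in self.is_a_edges()]
        )
        if edges.empty:
            edges = pd.DataFrame(columns=["subject", "predicate", "object"])
        return nodes, edges

    def write_tsv(self, node_path, edge_path) -> None:
        nodes, edges = self.to_frames()
        nodes.to_csv(node_path, sep="\t", index=False)
        edges.to_csv(edge_path, sep="\t", index=False)

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "Ontology":
        parents: dict[str, list[str]] = {}
        for row in edges.itertuples(index=False):
            if row.predicate == "subclass_of":
                parents.setdefault(row.subject, []).append(row.object)
        onto = cls()
        for row in nodes.itertuples(index=False):
            syn_field = getattr(row, "synonyms", "") or ""
            syns = tuple(s for s in str(syn_field).split("|") if s and s != "nan")
            onto.add(
                Term(
                    curie=row.id,
                    label=row.name,
                    branch=row.category,
                    parents=tuple(sorted(parents.get(row.id, []))),
                    synonyms=syns,
                )
            )
        return onto

    @classmethod
    def read_tsv(cls, node_path, edge_path) -> "Ontology":
        nodes = pd.read_csv(node_path, sep="\t", keep_default_na=False)
        edges = pd.read_csv(edge_path, sep="\t", keep_default_na=False)
        return cls.from_frames(nodes, edges)
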