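"""Translate survey questions and responses into ontology assertions.

Each survey question is aligned to ontology content through a *translation
key*: binary and ordinal-frequency questions map to a single CURIE, finite
categorical questions map each response option to its own CURIE, and
free-text questions are resolved at mapping time by a deterministic lexical
matcher over term labels and exact synonyms.

A positive response becomes a :class:`MappedAssertion` — a
(person, predicate, term) triple ready for knowledge-graph construction.
Negative and missing responses never produce assertions; responses that
cannot be resolved are collected in an unmapped-response report rather than
raised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .ontology import Ontology, is_curie

logger = logging.getLogger(__name__)

SURVEYS = ("health", "internal", "external")

#: predicate vocabulary, one per question-type transform
PREDICATES = (
    "has_phenotype",
    "has_disease",
    "affected_by",
    "consumes",
    "exposed_to",
    "undergone",
)

AFFIRMATIVE = {"yes", "y", "true", "1", 1, 1.0, True}
NEGATIVE = {"no", "n", "false", "0", 0, 0.0, False}


class ResponseType(str, Enum):
    binary = "binary"
    categorical = "categorical"
    ordinal_frequency = "ordinal_frequency"
    free_text = "free_text"


@dataclass(frozen=True)
class SurveyQuestion:
    question_id: str
    survey: str  # health | internal | external
    response_type: ResponseType
    topic: str = ""

    def __post_init__(self) -> None:
        if self.survey not in SURVEYS:
            raise ValueError(f"unknown survey {self.survey!r}")


@dataclass(frozen=True)
class ResponseRecord:
    """One answer of one respondent; ``value`` is None when missing."""

    respondent_id: str
    survey: str
    question_id: str
    value: object


@dataclass(frozen=True)
class MappedAssertion:
    respondent_id: str
    predicate: str
    object_curie: str
    value: object

    def __post_init__(self) -> None:
        if not is_curie(self.object_curie):
            raise ValueError(f"malformed CURIE {self.object_curie!r}")


@dataclass(frozen=True)
class KeyEntry:
    question_id: str
    response_type: ResponseType
    predicate: str
    curie: str | None = None          # binary / ordinal_frequency
    value_map: tuple[tuple[str, str], ...] = ()  # categorical: response -> CURIE
    free_text: bool = False


@dataclass
class TranslationKey:
    entries: dict[str, KeyEntry] = field(default_factory=dict)

    def __contains__(self, question_id: str) -> bool:
        return question_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, question_id: str) -> KeyEntry:
        return self.entries[question_id]

    def curies(self) -> set[str]:
        """All ontology CURIEs reachable through this key (free text excluded)."""
        out: set[str] = set()
        for e in self.entries.values():
            if e.curie:
                out.add(e.curie)
            out.update(c for _, c in e.value_map)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            if e.free_text:
                com = "@match"
            elif e.value_map:
                com = "|".join(f"{v}={c}" for v, c in e.value_map)
            else:
                com = e.curie
            rows.append(
                {"question_id": e.question_id, "response_type": e.response_type.value,
                 "predicate": e.predicate, "curie_or_map": com}
            )
        return pd.DataFrame(rows, columns=["question_id", "response_type",
                                           "predicate", "curie_or_map"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class TranslationKeyError(ValueError):
    pass


def load_translation_key(path, ontology: Ontology) -> TranslationKey:
    """Read and validate a translation-key TSV.

    Columns: ``question_id, response_type, predicate, curie_or_map``.  The
    last column holds a single CURIE (binary / ordinal), a
    ``value=CURIE|value=CURIE`` map (categorical), or ``@match`` (free text).
    Every CURIE must resolve in ``ontology``; duplicated question ids are an
    error.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.empty:
        warnings.warn(f"translation key {path} is empty", stacklevel=2)
        return TranslationKey()
    return translation_key_from_frame(frame, ontology)


def translation_key_from_frame(frame: pd.DataFrame, ontology: Ontology) -> TranslationKey:
    key = TranslationKey()
    bad: list[str] = []
    for row in frame.itertuples(index=False):
        qid = row.question_id
        if qid in key:
            raise TranslationKeyError(f"duplicate question_id {qid!r} in translation key")
        rtype = ResponseType(row.response_type)
        com = row.curie_or_map
        curie = None
        value_map: tuple[tuple[str, str], ...] = ()
        free_text = False
        if rtype is ResponseType.free_text or com == "@match":
            free_text = True
        elif rtype is ResponseType.categorical:
            pairs = []
            for chunk in com.split("|"):
                val, _, c = chunk.partition("=")
                if c not in ontology:
                    bad.append(f"{qid} → {c}")
                pairs.append((val, c))
            value_map = tuple(pairs)
        else:
            curie = com
            if curie not in ontology:
                bad.append(f"{qid} → {curie}")
        key.entries[qid] = KeyEntry(qid, rtype, row.predicate, curie, value_map, free_text)
    if bad:
        raise TranslationKeyError(
            "translation key references CURIEs absent from the ontology: "
            + "; ".join(bad)
        )
    return key


def match_free_text(text: str, ontology: Ontology) -> str | None:
    """Deterministic lexical entity resolution for a free-text response.

    The normalized text (case-folded, punctuation stripped) is compared
    exactly against term labels first, then against exact synonyms.  A
    unique hit returns its CURIE; zero hits or an ambiguous tie return None
    and are expected to surface in the unmapped report.
    """
    if not text or not str(text).strip():
        return None
    hits = ontology.label_matches(str(text))
    if not hits:
        hits = ontology.synonym_matches(str(text))
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:
        logger.info("ambiguous free-text response %r -> %s", text, hits)
    return None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or value == ""


def map_response(
    record: ResponseRecord,
    key: TranslationKey,
    ontology: Ontology,
    report: list | None = None,
) -> MappedAssertion | None:
    """Map a single response to an assertion, or None.

    Binary questions assert only on affirmative answers; ordinal-frequency
    answers are binarized at value > 0; categorical values are looked up in
    the per-question map; free text goes through :func:`match_free_text`.
    Unresolvable responses append a row to ``report`` instead of raising.
    """
    entry = key[record.question_id]
    value = record.value
    if _is_missing(value):
        return None

    def _report(reason: str) -> None:
        if report is not None:
            report.append(
                {"respondent_id": record.respondent_id,
                 "question_id": record.question_id,
                 "value": value, "reason": reason}
            )

    if entry.response_type is ResponseType.binary:
        norm = value.strip().casefold() if isinstance(value, str) else value
        if norm in AFFIRMATIVE:
            return MappedAssertion(record.respondent_id, entry.predicate, entry.curie, value)
        if norm not in NEGATIVE:
            _report("unrecognized binary value")
        return None

    if entry.response_type is ResponseType.ordinal_frequency:
        try:
            level = float(value)
        except (TypeError, ValueError):
            _report("non-numeric ordinal value")
            return None
        if level > 0:
            return MappedAssertion(record.respondent_id, entry.predicate, entry.curie, value)
        return None

    if entry.response_type is ResponseType.categorical:
        lookup = dict(entry.value_map)
        curie = lookup.get(str(value))
        if curie is None:
            _report("categorical value not in map")
            return None
        return MappedAssertion(record.respondent_id, entry.predicate, curie, value)

    # free text
    curie = match_free_text(str(value), ontology)
    if curie is None:
        _report("no unique lexical match")
        return None
    return MappedAssertion(record.respondent_id, entry.predicate, curie, value)


def map_responses(
    records,
    key: TranslationKey,
    ontology: Ontology,
) -> tuple[list[MappedAssertion], pd.DataFrame]:
    """Map a stream of responses; returns (assertions, unmapped report)."""
    report: list[dict] = []
    assertions = []
    for rec in records:
        if rec.question_id not in key:
            continue
        a = map_response(rec, key, ontology, report)
        if a is not None:
            assertions.append(a)
    report_frame = pd.DataFrame(
        report, columns=["respondent_id", "question_id", "value", "reason"]
    )
    return assertions, report_frame
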