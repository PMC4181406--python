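"""Term-annotated documents, vocabulary filtering and TF-IDF weighting.

A "phenotype" here is the weighted term-occurrence vector of one biomedical
document: either the descriptive record of a disease or a text record linked
to a gene (an abstract, an annotation note, a catalogue entry).  Documents
arrive already mapped to controlled-vocabulary terms — concept recognition is
upstream of this package — as sparse ``term_id -> count`` annotations plus a
term metadata table giving each term's source vocabularies (e.g. MeSH, ICD9CM,
GO) and its semantic type.

The processing pipeline implemented here is:

1. :func:`apply_filter` — restrict each document to one source vocabulary or
   to a whitelist of semantic types;
2. :func:`tfidf_weight` — weight the surviving counts by term frequency ×
   inverse document frequency, giving :class:`TermVector` profiles that live
   in a single vector space per corpus.

A small dictionary matcher (:func:`naive_concept_map`) is provided so that
free text can be annotated without any external concept-recognition engine;
it is deliberately simple (greedy leftmost-longest matching).
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "TermRecord",
    "DocumentAnnotation",
    "FilterMode",
    "VocabularyFilter",
    "TermVector",
    "DocumentCohort",
    "apply_filter",
    "document_frequencies",
    "inverse_document_frequencies",
    "weight_document",
    "tfidf_weight",
    "naive_concept_map",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermRecord:
    """One controlled-vocabulary term.

    Parameters
    ----------
    term_id
        Opaque unique identifier of the term.
    source_vocabs
        Non-empty set of vocabulary labels the term belongs to
        (e.g. ``{"MeSH", "ICD9CM"}``).
    semantic_type
        Single semantic-type label from a controlled list.
    """

    term_id: str
    source_vocabs: frozenset[str]
    semantic_type: str

    def __post_init__(self) -> None:
        if not self.source_vocabs:
            raise DataIntegrityError(
                f"term {self.term_id!r} has no source vocabularies")


@dataclass
class DocumentAnnotation:
    """Sparse term-occurrence counts of one document.

    ``counts`` maps ``term_id`` to a positive occurrence count; a document
    may legitimately be empty (e.g. after filtering).
    """

    doc_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, c in self.counts.items():
            if c < 1:
                raise DataIntegrityError(
                    f"document {self.doc_id!r}: count for term {term!r} "
                    f"is {c}, must be >= 1")

    @property
    def total(self) -> int:
        """Total term occurrences (document length in tokens)."""
        return sum(self.counts.values())


class FilterMode(Enum):
    BY_VOCAB = "by_vocab"
    BY_SEMANTIC_TYPES = "by_semantic_types"


@dataclass(frozen=True)
class VocabularyFilter:
    """Restriction of document terms to one vocabulary or a semantic-type set.

    Exactly the fields of the active mode are set; use the
    :meth:`by_vocab` / :meth:`by_semantic_types` constructors.
    """

    mode: FilterMode
    vocab: str | None = None
    allowed_semantic_types: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.mode is FilterMode.BY_VOCAB:
            if self.vocab is None or self.allowed_semantic_types is not None:
                raise ConfigurationError(
                    "BY_VOCAB filter requires vocab and no semantic types")
        else:
            if self.allowed_semantic_types is None or self.vocab is not None:
                raise ConfigurationError(
                    "BY_SEMANTIC_TYPES filter requires a semantic-type set "
                    "and no vocab")

    @classmethod
    def by_vocab(cls, vocab: str) -> "VocabularyFilter":
        return cls(mode=FilterMode.BY_VOCAB, vocab=vocab)

    @classmethod
    def by_semantic_types(cls, types: Iterable[str]) -> "VocabularyFilter":
        return cls(mode=FilterMode.BY_SEMANTIC_TYPES,
                   allowed_semantic_types=frozenset(types))


@dataclass
class TermVector:
    """Sparse non-negative weighted term profile of one document.

    Terms with weight exactly 0 are never stored; a term occurring in every
    document of the weighting cohort has idf 0 and is therefore absent.
    """

    doc_id: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # drop explicit zeros; negative weights are a construction bug
        zeros = [t for t, w in self.weights.items() if w == 0.0]
        for t in zeros:
            del self.weights[t]
        for t, w in self.weights.items():
            if w < 0:
                raise DataIntegrityError(
                    f"document {self.doc_id!r}: negative weight for {t!r}")

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass
class DocumentCohort:
    """The full corpus: annotations, term metadata and gene→document links."""

    annotations: list[DocumentAnnotation]
    term_table: dict[str, TermRecord]
    gene_links: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(self.annotations) < 2:
            raise DataIntegrityError(
                f"cohort has {len(self.annotations)} documents, need >= 2")
        doc_ids = [a.doc_id for a in self.annotations]
        if len(set(doc_ids)) != len(doc_ids):
            dupes = [d for d, c in Counter(doc_ids).items() if c > 1]
            raise DataIntegrityError(f"duplicate doc_ids in cohort: {dupes[:5]}")
        known = set(doc_ids)
        for gene, docs in self.gene_links.items():
            missing = docs - known
            if missing:
                raise DataIntegrityError(
                    f"gene {gene!r} links to unknown documents "
                    f"{sorted(missing)[:5]}")
        for ann in self.annotations:
            for term in ann.counts:
                if term not in self.term_table:
                    raise DataIntegrityError(
                        f"document {ann.doc_id!r} uses term {term!r} absent "
                        "from the term table")

    @property
    def n_documents(self) -> int:
        return len(self.annotations)

    @property
    def doc_ids(self) -> list[str]:
        return [a.doc_id for a in self.annotations]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_filter(
    annotations: Sequence[DocumentAnnotation],
    terms: Mapping[str, TermRecord],
    filt: VocabularyFilter,
) -> list[DocumentAnnotation]:
    """Restrict every document to the terms passing ``filt``.

    Counts are unchanged; documents left empty are retained (they stay in
    the cohort and will contribute similarity 0).  Idempotent.

    Raises
    ------
    ConfigurationError
        If a BY_VOCAB filter names a vocabulary not present in the term table.
    DataIntegrityError
        If an annotated term has no :class:`TermRecord`.
    """
    if filt.mode is FilterMode.BY_VOCAB:
        known_vocabs: set[str] = set()
        for rec in terms.values():
            known_vocabs |= rec.source_vocabs
        if filt.vocab not in known_vocabs:
            raise ConfigurationError(
                f"unknown vocabulary label {filt.vocab!r}; "
                f"term table covers {sorted(known_vocabs)}")

    out: list[DocumentAnnotation] = []
    for ann in annotations:
        kept: dict[str, int] = {}
        for term, count in ann.counts.items():
            rec = terms.get(term)
            if rec is None:
                raise DataIntegrityError(
                    f"term {term!r} (document {ann.doc_id!r}) is missing "
                    "from the term table")
            if filt.mode is FilterMode.BY_VOCAB:
                keep = filt.vocab in rec.source_vocabs
            else:
                keep = rec.semantic_type in filt.allowed_semantic_types  # type: ignore[operator]
            if keep:
                kept[term] = count
        out.append(DocumentAnnotation(doc_id=ann.doc_id, counts=kept))
    return out


# ---------------------------------------------------------------------------
# TF-IDF weighting
# ---------------------------------------------------------------------------

def document_frequencies(
    annotations: Sequence[DocumentAnnotation],
) -> Counter[str]:
    """Number of documents each term occurs in."""
    df: Counter[str] = Counter()
    for ann in annotations:
        df.update(ann.counts.keys())
    return df


def inverse_document_frequencies(
    annotations: Sequence[DocumentAnnotation],
) -> dict[str, float]:
    """idf(t) = ln(E_total / df(t)) over the given weighting cohort."""
    e_total = len(annotations)
    if e_total == 0:
        raise ConfigurationError("cannot compute idf on an empty cohort")
    return {t: math.log(e_total / df)
            for t, df in document_frequencies(annotations).items()}


def weight_document(
    ann: DocumentAnnotation,
    idf: Mapping[str, float],
) -> TermVector:
    """TF-IDF weight one document against a precomputed idf table.

    tf is the raw count divided by the document's total count; terms absent
    from ``idf`` (never seen in the weighting cohort) are dropped.  An empty
    document yields a zero vector.
    """
    total = ann.total
    if total == 0:
        return TermVector(doc_id=ann.doc_id, weights={})
    weights = {}
    for term, count in ann.counts.items():
        idf_t = idf.get(term)
        if idf_t is None or idf_t == 0.0:
            continue
        weights[term] = (count / total) * idf_t
    return TermVector(doc_id=ann.doc_id, weights=weights)


def tfidf_weight(
    annotations: Sequence[DocumentAnnotation],
    idf: Mapping[str, float] | None = None,
) -> list[TermVector]:
    """TF-IDF weight a cohort of documents.

    weight(t, d) = (count(t, d) / len(d)) * ln(E_total / df(t)),
    with df counted on ``annotations`` themselves unless an external ``idf``
    table is supplied (used to place a disease document in the same vector
    space as the gene-document cohort it is compared against).

    Deterministic and invariant to document order.
    """
    if len(annotations) == 0:
        raise ConfigurationError("cannot TF-IDF weight an empty cohort")
    if idf is None:
        idf = inverse_document_frequencies(annotations)
    return [weight_document(a, idf) for a in annotations]


# ---------------------------------------------------------------------------
# Dictionary matcher (stand-in for a full concept-recognition engine)
# ---------------------------------------------------------------------------

def naive_concept_map(
    text: str,
    dictionary: Mapping[str, str],
    doc_id: str = "query",
) -> DocumentAnnotation:
    """Greedy leftmost-longest dictionary matching of free text.

    ``dictionary`` maps lowercase surface forms to term ids.  Matching is
    case-insensitive and bounded by word boundaries; overlapping candidate
    matches are resolved leftmost-longest.  No matches yields an empty
    annotation.
    """
    if not text or not dictionary:
        return DocumentAnnotation(doc_id=doc_id, counts={})
    # longest-first alternation makes the regex engine pick the longest
    # surface form at each leftmost starting position
    forms = sorted(dictionary, key=len, reverse=True)
    pattern = re.compile(
        r"(?<!\w)(?:" + "|".join(re.escape(f) for f in forms) + r")(?!\w)",
        re.IGNORECASE,
    )
    counts: Counter[str] = Counter()
    for match in pattern.finditer(text):
        counts[dictionary[match.group(0).lower()]] += 1
    return DocumentAnnotation(doc_id=doc_id, counts=dict(counts))
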