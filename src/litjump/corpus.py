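"""Corpus ingestion, tokenization and dictionary-based entity recognition.

Abstracts arrive as dated records (MEDLINE XML or line-delimited JSON); each
becomes a :class:`Document` holding a normalized token stream and the set of
dictionary entities (proteins, disease terms) mentioned in it.  All
downstream statistics are document-level presence/absence, so mentions are
kept as a set — how many times a protein is repeated inside one abstract
never matters.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

PROTEIN = "protein"
DISEASE = "disease"

# Word tokens: runs of unicode word characters (letters incl. Greek, digits)
# optionally joined by internal hyphens.  Punctuation at token boundaries is
# dropped; internal hyphens survive ("homa-ir").
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)

#: Monday of ISO week 1, 1970 — origin for the global week index.
_WEEK_EPOCH = _dt.date(1970, 1, 5)


def tokenize(text: str) -> list[str]:
    """Normalize free text into word tokens.

    Lowercases, strips punctuation at token boundaries, keeps digits and
    Greek letters, and preserves internal hyphens.  Deterministic and
    idempotent on its own output; empty text yields an empty list.
    """
    if not text:
        return []
    return _TOKEN_RE.findall(text.lower())


def week_index(date: _dt.date) -> int:
    """Map a calendar date to a global integer week index.

    Weeks are ISO weeks (Monday-aligned) counted from the first ISO week of
    1970, so the index is monotone with calendar time.
    """
    idx = (date - _WEEK_EPOCH).days // 7
    if idx < 0:
        raise ValueError(f"date {date} precedes the week-index epoch")
    return idx


@dataclass(frozen=True)
class Document:
    """One dated abstract: identifier, entry week, tokens and entity mentions.

    ``tokens`` is the concatenated title + abstract after :func:`tokenize`;
    ``mentions`` holds ``(entity_id, entity_class)`` pairs found by NER.
    """

    doc_id: str
    week: int
    tokens: tuple[str, ...]
    mentions: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError("week index must be >= 0")
        if any(t == "" for t in self.tokens):
            raise ValueError("tokens must not contain empty strings")

    def entities(self, entity_class: str) -> set[str]:
        """Ids of mentioned entities of one class."""
        return {eid for eid, cls in self.mentions if cls == entity_class}

    def with_mentions(self, mentions: Iterable[tuple[str, str]]) -> "Document":
        return Document(self.doc_id, self.week, self.tokens, frozenset(mentions))


class EntityDictionary:
    """Synonym dictionary mapping token sequences to (entity_id, entity_class).

    Matching is case-insensitive by default (synonyms are normalized through
    :func:`tokenize` on load).  A synonym may not map to two different
    entities; every synonym must have at least one token.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, ...], tuple[str, str]] | None = None,
        case_insensitive: bool = True,
    ) -> None:
        self.case_insensitive = case_insensitive
        self._entries: dict[tuple[str, ...], tuple[str, str]] = {}
        self._max_len = 0
        if entries:
            for syn, (eid, cls) in entries.items():
                self.add(syn, eid, cls)

    def add(self, synonym: Sequence[str] | str, entity_id: str, entity_class: str) -> None:
        if isinstance(synonym, str):
            toks = tuple(tokenize(synonym) if self.case_insensitive else synonym.split())
        else:
            toks = tuple(
                t.lower() for t in synonym) if self.case_insensitive else tuple(synonym)
        if not toks:
            raise ValueError(f"synonym for {entity_id!r} has no tokens")
        prev = self._entries.get(toks)
        if prev is not None and prev[0] != entity_id:
            raise ValueError(
                f"synonym {' '.join(toks)!r} maps to both {prev[0]!r} and {entity_id!r}")
        self._entries[toks] = (entity_id, entity_class)
        self._max_len = max(self._max_len, len(toks))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, synonym: tuple[str, ...]) -> bool:
        return tuple(synonym) in self._entries

    def lookup(self, synonym: tuple[str, ...]) -> tuple[str, str] | None:
        return self._entries.get(tuple(synonym))

    @property
    def max_synonym_length(self) -> int:
        return self._max_len

    def entity_ids(self, entity_class: str | None = None) -> set[str]:
        return {
            eid for eid, cls in self._entries.values()
            if entity_class is None or cls == entity_class
        }

    @classmethod
    def from_tsv(cls, path: str | Path, case_insensitive: bool = True) -> "EntityDictionary":
        """Load a dictionary from TSV columns: entity_id, entity_class, synonym."""
        d = cls(case_insensitive=case_insensitive)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                eid, cls_, syn = parts
                if lineno == 1 and eid == "entity_id":
                    continue  # header row
                d.add(syn, eid, cls_)
        return d

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tentity_class\tsynonym\n")
            for toks, (eid, cls_) in sorted(self._entries.items()):
                fh.write(f"{eid}\t{cls_}\t{' '.join(toks)}\n")


def match_entities(
    tokens: Sequence[str], dictionary: EntityDictionary
) -> frozenset[tuple[str, str]]:
    """Find dictionary entities in a token sequence.

    Scans left to right taking the longest dictionary synonym starting at each
    position; matched spans do not overlap.  Duplicate mentions collapse to a
    single ``(entity_id, entity_class)`` entry.
    """
    if len(dictionary) == 0:
        raise ValueError("entity dictionary is empty")
    found: set[tuple[str, str]] = set()
    i, n = 0, len(tokens)
    max_len = dictionary.max_synonym_length
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            entry = dictionary.lookup(tuple(tokens[i:i + length]))
            if entry is not None:
                hit = (entry, length)
                break
        if hit is not None:
            found.add(hit[0])
            i += hit[1]
        else:
            i += 1
    return frozenset(found)


def annotate(docs: Iterable[Document], *dictionaries: EntityDictionary) -> list[Document]:
    """Attach NER mentions from one or more dictionaries to every document."""
    out = []
    for doc in docs:
        mentions: set[tuple[str, str]] = set(doc.mentions)
        for d in dictionaries:
            mentions |= match_entities(doc.tokens, d)
        out.append(doc.with_mentions(mentions))
    return out


class CorpusFormatError(ValueError):
    """Raised when a corpus file does not parse in the declared dialect."""


def _record_to_document(
    doc_id: str, week: int | None, date: _dt.date | None,
    title: str | None, abstract: str | None,
) -> Document | None:
    """Build a Document, or None when title/abstract is missing (skipped)."""
    if not title or not abstract:
        return None
    if week is None:
        if date is None:
            raise CorpusFormatError(f"record {doc_id!r}: neither week nor date given")
        week = week_index(date)
    toks = tuple(tokenize(title) + tokenize(abstract))
    return Document(doc_id=doc_id, week=week, tokens=toks)


def _iter_jsonl(path: Path) -> Iterator[Document | None]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON record") from exc
            if "doc_id" not in rec:
                raise CorpusFormatError(f"{path}:{lineno}: record lacks doc_id")
            if "tokens" in rec:
                # pre-normalized dialect: tokens (and mentions) stored directly
                yield Document(
                    doc_id=str(rec["doc_id"]),
                    week=int(rec["week"]),
                    tokens=tuple(rec["tokens"]),
                    mentions=frozenset(tuple(m) for m in rec.get("mentions", [])),
                )
                continue
            date = rec.get("date")
            yield _record_to_document(
                str(rec["doc_id"]),
                rec.get("week"),
                _dt.date.fromisoformat(date) if date else None,
                rec.get("title"),
                rec.get("abstract"),
            )


def _iter_medline_xml(path: Path) -> Iterator[Document | None]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"{path}: malformed XML: {exc}") from exc
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if pmid is None:
            raise CorpusFormatError(f"{path}: PubmedArticle record lacks PMID")
        title = art.findtext(".//ArticleTitle")
        abstract_parts = [t for t in (
            el.text for el in art.iter("AbstractText")) if t]
        abstract = " ".join(abstract_parts) if abstract_parts else None
        week_el = art.findtext(".//WeekIndex")
        date_el = art.find(".//DateRevised")
        date = None
        if date_el is not None:
            try:
                date = _dt.date(
                    int(date_el.findtext("Year")),
                    int(date_el.findtext("Month")),
                    int(date_el.findtext("Day")),
                )
            except (TypeError, ValueError) as exc:
                raise CorpusFormatError(
                    f"{path}: PMID {pmid}: bad DateRevised") from exc
        yield _record_to_document(
            pmid, int(week_el) if week_el is not None else None, date,
            title, abstract)


_READERS = {"records_jsonl": _iter_jsonl, "medline_xml": _iter_medline_xml}


def read_corpus(path: str | Path, format: str = "records_jsonl") -> list[Document]:
    """Read a corpus file into Documents.

    Records missing a title or an abstract are skipped; the skip count is
    logged (only records with both fields are mined).  Unknown ``format``
    raises a configuration error; malformed files raise
    :class:`CorpusFormatError` naming the first bad record.
    """
    reader = _READERS.get(format)
    if reader is None:
        raise ValueError(
            f"unknown corpus format {format!r}; expected one of {sorted(_READERS)}")
    docs: list[Document] = []
    skipped = 0
    for doc in reader(Path(path)):
        if doc is None:
            skipped += 1
        else:
            docs.append(doc)
    logger.info("read %d documents from %s (skipped %d lacking title/abstract)",
                len(docs), path, skipped)
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents in the pre-normalized line-delimited dialect.

    Stores tokens and mentions explicitly so that reading the file back
    yields field-identical documents.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "week": doc.week,
                "tokens": list(doc.tokens),
                "mentions": sorted(list(m) for m in doc.mentions),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
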