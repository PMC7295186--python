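"""Frequent n-gram extraction and disease over-representation filtering.

The terminology is learned from the corpus itself: every contiguous token
window of length n (within the configured range) that occurs in enough
documents and does not start or end with a stopword becomes an n-gram with
an exact posting set.  A second pass keeps only n-grams over-represented in
disease-mentioning documents — those are the candidates for semantic
concepts.

n-grams are counted by document presence, not token frequency, because every
downstream statistic (context over-representation, concept weights, article
scores) is document-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .association import ContingencyTable2x2, fisher_exact_p
from .corpus import Document

logger = logging.getLogger(__name__)

NGramKey = tuple[str, ...]


def default_stopwords() -> frozenset[str]:
    """The packaged stopword list (one word per line, # comments)."""
    text = resources.files(__package__).joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        w for w in (line.strip() for line in text.splitlines())
        if w and not w.startswith("#"))


def load_stopwords(path: str | Path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            w for w in (line.strip() for line in fh) if w and not w.startswith("#"))


@dataclass(frozen=True)
class NGram:
    """A normalized word sequence with its exact document posting set."""

    tokens: NGramKey
    postings: frozenset[str]

    @property
    def df(self) -> int:
        return len(self.postings)

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass
class NGramCatalog:
    """All retained n-grams of a corpus plus corpus-level counts.

    After :func:`disease_overrepresented` the catalog additionally carries
    per-n-gram over-representation ratios and filter p-values.
    """

    ngrams: dict[NGramKey, NGram]
    D: int
    disease_df: int = 0
    ratios: dict[NGramKey, float] = field(default_factory=dict)
    pvalues: dict[NGramKey, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ngrams)

    def __contains__(self, key: NGramKey) -> bool:
        return tuple(key) in self.ngrams

    def __getitem__(self, key: NGramKey) -> NGram:
        return self.ngrams[tuple(key)]

    def keys(self):
        return self.ngrams.keys()

    def values(self):
        return self.ngrams.values()


def iter_windows(tokens: Sequence[str], n_range: tuple[int, int]) -> Iterable[NGramKey]:
    """All contiguous token windows with lengths in the closed range."""
    lo, hi = n_range
    L = len(tokens)
    for n in range(lo, hi + 1):
        for i in range(L - n + 1):
            yield tuple(tokens[i:i + n])


def extract_ngrams(
    docs: Sequence[Document],
    n_range: tuple[int, int] = (2, 6),
    min_df: int = 5,
    stopwords: frozenset[str] | None = None,
) -> NGramCatalog:
    """Extract the frequent-n-gram catalog of a corpus.

    Keeps every window of length in ``n_range`` that occurs in at least
    ``min_df`` documents and neither starts nor ends with a stopword.
    Postings record the exact set of containing documents.
    """
    lo, hi = n_range
    if not (1 <= lo <= hi <= 8):
        raise ValueError("n_range must satisfy 1 <= lo <= hi <= 8")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if stopwords is None:
        stopwords = default_stopwords()
    postings: dict[NGramKey, set[str]] = {}
    for doc in docs:
        seen: set[NGramKey] = set()
        for win in iter_windows(doc.tokens, n_range):
            if win[0] in stopwords or win[-1] in stopwords:
                continue
            seen.add(win)
        for win in seen:
            postings.setdefault(win, set()).add(doc.doc_id)
    ngrams = {
        key: NGram(tokens=key, postings=frozenset(docs_))
        for key, docs_ in postings.items() if len(docs_) >= min_df
    }
    logger.info("extracted %d n-grams (of %d candidate windows) from %d docs",
                len(ngrams), len(postings), len(docs))
    return NGramCatalog(ngrams=ngrams, D=len(docs))


def overrepresentation_ratio(co: int, df_a: int, df_b: int, D: int) -> float:
    """Observed/expected co-document ratio for two terms under independence."""
    if df_a == 0 or df_b == 0:
        raise ValueError("document frequencies must be positive")
    return (co * D) / (df_a * df_b)


def disease_overrepresented(
    catalog: NGramCatalog,
    disease_doc_ids: Iterable[str],
    min_co: int = 3,
    min_ratio: float = 2.0,
    alpha: float = 0.01,
) -> NGramCatalog:
    """Keep n-grams over-represented in disease-mentioning documents.

    An n-gram survives when its disease co-document count is at least
    ``min_co``, its over-representation ratio (obs_co * D)/(df * disease_df)
    is at least ``min_ratio``, and the one-sided Fisher p-value is at most
    ``alpha``.  Ratios and p-values are attached to the returned catalog.
    """
    disease_docs = set(disease_doc_ids)
    disease_df = len(disease_docs)
    if disease_df == 0:
        raise ValueError("no disease-mentioning documents: cannot filter")
    D = catalog.D
    kept: dict[NGramKey, NGram] = {}
    ratios: dict[NGramKey, float] = {}
    pvalues: dict[NGramKey, float] = {}
    for key, ng in catalog.ngrams.items():
        co = len(ng.postings & disease_docs)
        if co < min_co:
            continue
        ratio = overrepresentation_ratio(co, ng.df, disease_df, D)
        if ratio < min_ratio:
            continue
        table = ContingencyTable2x2(
            a=co, b=ng.df - co, c=disease_df - co, d=D - ng.df - disease_df + co)
        p = fisher_exact_p(table, side="greater")
        if p > alpha:
            continue
        kept[key] = ng
        ratios[key] = ratio
        pvalues[key] = p
    logger.info("disease filter kept %d of %d n-grams (disease_df=%d)",
                len(kept), len(catalog), disease_df)
    return NGramCatalog(ngrams=kept, D=D, disease_df=disease_df,
                        ratios=ratios, pvalues=pvalues)


def write_ngrams_tsv(catalog: NGramCatalog, path: str | Path) -> None:
    """TSV report: ngram, n, df, disease_co, ratio, p_value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ngram\tn\tdf\tratio\tp_value\n")
        for key in sorted(catalog.keys()):
            ng = catalog[key]
            ratio = catalog.ratios.get(key, float("nan"))
            p = catalog.pvalues.get(key, float("nan"))
            fh.write(f"{ng.text}\t{ng.n}\t{ng.df}\t{ratio:.4g}\t{p:.4g}\n")
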