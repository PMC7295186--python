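"""Concept weights, article scores and windowed protein relevance.

The scoring chain: each semantic concept is weighted by how much more often
than expected it is co-mentioned with the K core proteins (average log10
observed/expected ratio — pointwise mutual information averaged over the
core set); an article scores the sum of the weights of the distinct concepts
it contains; a protein's weekly score is the best article mentioning it that
week; and its combined relevance blends the top M weekly scores of the
trailing W-week window, heaviest weight on the highest, so that relevance
must be sustained over time rather than coming from one conference week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .association import CoreProteinSet
from .concepts import SemanticConcept
from .corpus import PROTEIN, Document
from .ngrams import NGramCatalog, NGramKey

logger = logging.getLogger(__name__)

#: Five-year window length in weeks.
DEFAULT_WINDOW = 260
#: Number of top weekly scores blended into the combined relevance.
DEFAULT_TOP_M = 40


@dataclass(frozen=True)
class ConceptWeight:
    """Per-core-protein PMI values and their mean for one concept."""

    concept_id: str
    per_protein_pmi: dict[str, float]
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError("concept weight must be finite")


def concept_weight(
    concept: SemanticConcept,
    core: CoreProteinSet,
    docs: Sequence[Document],
    catalog: NGramCatalog,
    zero_floor: float = 0.5,
) -> ConceptWeight:
    """Average pointwise mutual information of a concept with the core set.

    For each core protein p: ``obs_p`` is the number of documents mentioning
    p and containing any member n-gram, ``exp_p = df_concept * df_p / D``
    the count expected under independence, and ``pmi_p = log10(obs_p /
    exp_p)`` with ``obs_p`` floored at ``zero_floor`` when zero so the PMI
    stays finite.  The weight is the arithmetic mean over all K core
    proteins: a weight of 1 means the concept is co-mentioned ten times as
    often as expected by random.
    """
    concept_postings: set[str] = set()
    for key in concept.members:
        concept_postings |= catalog[key].postings
    if not concept_postings:
        raise ValueError(f"concept {concept.concept_id} has no postings")
    protein_docs: dict[str, set[str]] = {pid: set() for pid in core.ids}
    for doc in docs:
        for eid, cls in doc.mentions:
            if cls == PROTEIN and eid in protein_docs:
                protein_docs[eid].add(doc.doc_id)
    return _concept_weight_from_postings(
        concept, concept_postings, protein_docs, len(docs), zero_floor)


def _concept_weight_from_postings(
    concept: SemanticConcept,
    concept_postings: set[str],
    protein_docs: Mapping[str, set[str]],
    D: int,
    zero_floor: float,
) -> ConceptWeight:
    df_concept = len(concept_postings)
    pmi: dict[str, float] = {}
    for pid, pdocs in protein_docs.items():
        df_p = len(pdocs)
        if df_p == 0:
            raise ValueError(
                f"core protein {pid!r} unseen in the corpus; core selection "
                "should precede weighting")
        obs = len(concept_postings & pdocs)
        exp = df_concept * df_p / D
        pmi[pid] = float(np.log10(max(obs, zero_floor if obs == 0 else obs) / exp))
    weight = float(np.mean(list(pmi.values())))
    return ConceptWeight(concept_id=concept.concept_id,
                         per_protein_pmi=pmi, weight=weight)


def weight_concepts(
    concepts: Iterable[SemanticConcept],
    core: CoreProteinSet,
    docs: Sequence[Document],
    catalog: NGramCatalog,
    zero_floor: float = 0.5,
) -> list[SemanticConcept]:
    """Assign PMI-based weights to every concept (in place) and return them.

    Shares one pass over the corpus for the protein posting sets.
    """
    protein_docs: dict[str, set[str]] = {pid: set() for pid in core.ids}
    for doc in docs:
        for eid, cls in doc.mentions:
            if cls == PROTEIN and eid in protein_docs:
                protein_docs[eid].add(doc.doc_id)
    out = []
    for concept in concepts:
        postings: set[str] = set()
        for key in concept.members:
            postings |= catalog[key].postings
        cw = _concept_weight_from_postings(
            concept, postings, protein_docs, len(docs), zero_floor)
        concept.weight = cw.weight
        out.append(concept)
    return out


@dataclass(frozen=True)
class ArticleScore:
    """An article's relevance score with its per-concept breakdown."""

    doc_id: str
    score: float
    contributions: tuple[tuple[str, float], ...]  # (concept_id, weight), desc


class ConceptMatcher:
    """Fast lookup from documents to the concepts they contain.

    Indexes every member n-gram of every weighted concept; a concept
    contributes once per article no matter how many of its members (or
    member repetitions) occur.
    """

    def __init__(self, concepts: Iterable[SemanticConcept]) -> None:
        self._member_to_concept: dict[NGramKey, SemanticConcept] = {}
        self._lengths: set[int] = set()
        for c in concepts:
            if c.weight is None:
                raise ValueError(f"concept {c.concept_id} has no weight yet")
            for key in c.members:
                self._member_to_concept[key] = c
                self._lengths.add(len(key))

    def concepts_in(self, tokens: Sequence[str]) -> list[SemanticConcept]:
        found: dict[str, SemanticConcept] = {}
        L = len(tokens)
        for n in sorted(self._lengths):
            for i in range(L - n + 1):
                c = self._member_to_concept.get(tuple(tokens[i:i + n]))
                if c is not None:
                    found[c.concept_id] = c
        return list(found.values())


def score_article(doc: Document, matcher: ConceptMatcher) -> ArticleScore:
    """Sum the weights of the distinct concepts present in the document."""
    present = matcher.concepts_in(doc.tokens)
    contributions = tuple(sorted(
        ((c.concept_id, float(c.weight)) for c in present),
        key=lambda t: (-t[1], t[0])))
    return ArticleScore(doc_id=doc.doc_id,
                        score=float(sum(w for _, w in contributions)),
                        contributions=contributions)


def score_articles(
    docs: Sequence[Document], concepts: Iterable[SemanticConcept]
) -> dict[str, ArticleScore]:
    matcher = ConceptMatcher(concepts)
    return {doc.doc_id: score_article(doc, matcher) for doc in docs}


def weekly_protein_scores(
    docs: Sequence[Document], article_scores: Mapping[str, ArticleScore]
) -> dict[str, float]:
    """Per-protein maximum article score among the given (one week's) docs.

    Proteins not mentioned that week are absent (windows treat them as 0).
    """
    best: dict[str, float] = {}
    for doc in docs:
        s = article_scores[doc.doc_id].score
        for pid in doc.entities(PROTEIN):
            if s > best.get(pid, -np.inf):
                best[pid] = s
    return best


def weekly_scores_by_week(
    docs: Sequence[Document], article_scores: Mapping[str, ArticleScore]
) -> dict[int, dict[str, float]]:
    """Group documents by week and take per-protein weekly maxima."""
    by_week: dict[int, list[Document]] = {}
    for doc in docs:
        by_week.setdefault(doc.week, []).append(doc)
    return {w: weekly_protein_scores(ds, article_scores)
            for w, ds in sorted(by_week.items())}


def top_m_weights(M: int) -> np.ndarray:
    """Linearly decreasing weights u_i = (M+1-i)/sum, i = 1..M; sums to 1."""
    u = np.arange(M, 0, -1, dtype=float)
    return u / u.sum()


def combined_relevance(
    weekly: Mapping[int, float], week: int,
    W: int = DEFAULT_WINDOW, M: int = DEFAULT_TOP_M,
) -> float:
    """Windowed protein relevance at ``week``.

    Takes the W weekly scores ending at ``week`` (missing weeks count 0),
    sorts them descending, and returns the weighted sum of the top M with
    linearly decreasing weights.  Invariant to the order of weeks inside
    the window.
    """
    if W < M:
        raise ValueError("window length W must be >= M")
    if week < 0:
        raise ValueError("week must be >= 0")
    window = [weekly.get(w, 0.0) for w in range(week - W + 1, week + 1)]
    top = np.sort(np.asarray(window))[::-1][:M]
    return float(np.dot(top_m_weights(M), top))


def rank_proteins(scores: Mapping[str, float]) -> dict[str, int]:
    """Rank proteins by combined score; 1 = most relevant.

    Ties are broken by ascending protein id; the ranks form a permutation
    of 1..N.
    """
    if not scores:
        raise ValueError("no scored proteins to rank")
    ordered = sorted(scores, key=lambda pid: (-scores[pid], pid))
    return {pid: r for r, pid in enumerate(ordered, 1)}


@dataclass
class ProteinRelevanceSeries:
    """Weekly, combined and rank trajectories for one protein."""

    protein_id: str
    weekly_scores: dict[int, float]
    combined: dict[int, float] = field(default_factory=dict)
    rank: dict[int, int] = field(default_factory=dict)


def relevance_timeline(
    weekly_by_week: Mapping[int, Mapping[str, float]],
    proteins: Iterable[str],
    weeks: Sequence[int],
    W: int = DEFAULT_WINDOW,
    M: int = DEFAULT_TOP_M,
) -> dict[str, ProteinRelevanceSeries]:
    """Combined scores and weekly ranks for a protein universe.

    Proteins never mentioned score 0 and rank behind every scored protein
    (deterministically by id).
    """
    proteins = sorted(set(proteins))
    series = {
        pid: ProteinRelevanceSeries(
            pid, {w: m.get(pid, 0.0) for w, m in weekly_by_week.items()
                  if pid in m})
        for pid in proteins
    }
    for w in weeks:
        combined = {
            pid: combined_relevance(series[pid].weekly_scores, w, W=W, M=M)
            for pid in proteins
        }
        ranks = rank_proteins(combined)
        for pid in proteins:
            series[pid].combined[w] = combined[pid]
            series[pid].rank[w] = ranks[pid]
    return series


def rank_fold_change(initial_rank: int, final_rank: int) -> float:
    """Fold improvement initial/final, rounded half-up to one decimal."""
    if initial_rank < 1 or final_rank < 1:
        raise ValueError("ranks must be >= 1")
    fc = Decimal(initial_rank) / Decimal(final_rank)
    return float(fc.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def evaluate_roc(
    scores: Mapping[str, float], positives: Iterable[str]
) -> tuple[float, np.ndarray]:
    """ROC evaluation of a protein scoring against a benchmark set.

    The AUC uses the rank-sum (Mann–Whitney) formulation with midranks for
    ties; the returned array holds (fpr, tpr) points for plotting.
    """
    positives = set(positives)
    pids = sorted(scores)
    labels = np.array([pid in positives for pid in pids])
    if labels.all() or not labels.any():
        raise ValueError("positive set must be non-empty and a strict subset")
    vals = np.array([scores[pid] for pid in pids], dtype=float)
    ranks = rankdata(vals)  # midranks
    n_pos = int(labels.sum())
    n_neg = len(pids) - n_pos
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels.astype(int), vals)
    return float(auc), np.column_stack([fpr, tpr])
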