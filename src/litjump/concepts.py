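"""Grouping n-grams into semantic concepts.

Two complementary similarity measures are combined:

* **string similarity** absorbs spelling variants and word rearrangements
  ("type 2 diabetes" vs "diabetes type ii");
* **context similarity** links n-grams that are co-mentioned with the same
  set of other n-grams, even when they never co-occur themselves ("leptin
  treatment" vs "elevated leptin").

An edge joins two n-grams when either measure passes its threshold; the
Markov cluster algorithm (MCL) then partitions the weighted graph into
semantic concepts, each represented by its most frequent member n-gram.
Concepts may legitimately contain antonymic phrases ("increased glucose",
"decreased glucose"): polarity is not part of the similarity notion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import networkx as nx
import numpy as np
import scipy.sparse as sp

from .ngrams import NGramCatalog, NGramKey

logger = logging.getLogger(__name__)

# Small roman numerals aliased to arabic digits during token comparison.
_ROMAN = {"i": "1", "ii": "2", "iii": "3", "iv": "4", "v": "5",
          "vi": "6", "vii": "7", "viii": "8", "ix": "9", "x": "10"}


def _normalize_numeral(token: str) -> str:
    return _ROMAN.get(token, token)


def _tokens_match(a: str, b: str) -> bool:
    """Token equivalence: equal after numeral aliasing, or within one edit
    for tokens of length >= 4."""
    a_n, b_n = _normalize_numeral(a), _normalize_numeral(b)
    if a_n == b_n:
        return True
    if len(a) >= 4 and len(b) >= 4:
        return edlib.align(a, b, task="distance", k=1)["editDistance"] != -1
    return False


def string_similarity(a: Sequence[str], b: Sequence[str]) -> float:
    """Order-invariant token-set similarity between two n-grams.

    Tokens are paired one-to-one by maximum bipartite matching under
    :func:`_tokens_match`; the similarity is the matched-token count divided
    by the longer n-gram's length.  Symmetric, in [0, 1], and 1.0 for
    identical or merely rearranged n-grams.
    """
    if not a or not b:
        return 0.0
    match = np.zeros((len(a), len(b)), dtype=float)
    for i, ta in enumerate(a):
        for j, tb in enumerate(b):
            if _tokens_match(ta, tb):
                match[i, j] = 1.0
    if not match.any():
        return 0.0
    from scipy.optimize import linear_sum_assignment
    rows, cols = linear_sum_assignment(-match)
    matched = match[rows, cols].sum()
    return float(matched / max(len(a), len(b)))


@dataclass
class ContextMatrix:
    """Pairwise over-representation ratios between catalog n-grams.

    ``matrix[i, j] = co_docs(i, j) * D / (df_i * df_j)``, zero when the two
    n-grams never share a document; the diagonal equals ``D / df_i``.
    """

    keys: tuple[NGramKey, ...]
    index: dict[NGramKey, int]
    matrix: sp.csr_matrix

    def row(self, key_or_idx) -> np.ndarray:
        i = key_or_idx if isinstance(key_or_idx, int) else self.index[key_or_idx]
        return np.asarray(self.matrix.getrow(i).todense()).ravel()


def context_overrepresentation_matrix(catalog: NGramCatalog) -> ContextMatrix:
    """Build the symmetric n-gram co-mention over-representation matrix."""
    keys = tuple(sorted(catalog.keys()))
    index = {k: i for i, k in enumerate(keys)}
    doc_index: dict[str, int] = {}
    rows, cols = [], []
    for j, key in enumerate(keys):
        for doc_id in catalog[key].postings:
            rows.append(doc_index.setdefault(doc_id, len(doc_index)))
            cols.append(j)
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(doc_index), len(keys)))
    co = (X.T @ X).tocsr()  # co-document counts; diagonal = df
    df = np.array([catalog[k].df for k in keys], dtype=float)
    inv = sp.diags(1.0 / df)
    ratio = (inv @ co @ inv) * catalog.D
    return ContextMatrix(keys=keys, index=index, matrix=ratio.tocsr())


def context_similarity(ctx: ContextMatrix, i, j) -> float:
    """Cosine similarity of two matrix rows after log1p, excluding the two
    n-grams' own columns.

    In [0, 1] since all entries are non-negative; an all-zero row (after
    exclusion) gives 0.
    """
    ii = i if isinstance(i, int) else ctx.index[i]
    jj = j if isinstance(j, int) else ctx.index[j]
    ri = np.log1p(ctx.row(ii))
    rj = np.log1p(ctx.row(jj))
    ri[[ii, jj]] = 0.0
    rj[[ii, jj]] = 0.0
    ni, nj = np.linalg.norm(ri), np.linalg.norm(rj)
    if ni == 0.0 or nj == 0.0:
        logger.debug("all-zero context row for pair (%s, %s); similarity 0", i, j)
        return 0.0
    return float(np.dot(ri, rj) / (ni * nj))


def _all_pairs_context_similarity(ctx: ContextMatrix) -> np.ndarray:
    """Vectorized context similarity for every pair.

    Uses the Gram matrix of the log1p-transformed rows with per-pair
    corrections for the two excluded columns; algebraically identical to
    calling :func:`context_similarity` on each pair.
    """
    L = np.log1p(np.asarray(ctx.matrix.todense()))
    n = L.shape[0]
    G = L @ L.T
    sq = np.einsum("ij,ij->i", L, L)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = G[i, j] - L[i, i] * L[j, i] - L[i, j] * L[j, j]
            ni2 = sq[i] - L[i, i] ** 2 - L[i, j] ** 2
            nj2 = sq[j] - L[j, i] ** 2 - L[j, j] ** 2
            if ni2 <= 0.0 or nj2 <= 0.0:
                continue
            sim[i, j] = sim[j, i] = max(0.0, num / np.sqrt(ni2 * nj2))
    return sim


def build_similarity_graph(
    catalog: NGramCatalog,
    string_threshold: float = 0.8,
    context_threshold: float = 0.5,
    lam: float = 0.5,
) -> nx.Graph:
    """Build the n-gram similarity graph used by MCL.

    An (undirected) edge joins n-grams i and j when the string similarity
    reaches ``string_threshold`` **or** the context similarity reaches
    ``context_threshold`` — both measures act simultaneously through the
    union rule and through the combined edge weight
    ``lam * w_string + (1 - lam) * w_context``.  Nodes carry their document
    frequency and postings for later cluster summarization.
    """
    for name, t in (("string_threshold", string_threshold),
                    ("context_threshold", context_threshold), ("lam", lam)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    ctx = context_overrepresentation_matrix(catalog)
    keys = ctx.keys
    g = nx.Graph()
    for key in keys:
        ng = catalog[key]
        g.add_node(key, df=ng.df, postings=ng.postings)
    csim = _all_pairs_context_similarity(ctx)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            w_s = string_similarity(keys[i], keys[j])
            w_c = csim[i, j]
            if w_s >= string_threshold or w_c >= context_threshold:
                g.add_edge(keys[i], keys[j], w_string=w_s, w_context=w_c,
                           w_combined=lam * w_s + (1.0 - lam) * w_c)
    logger.info("similarity graph: %d nodes, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    return g


@dataclass
class SemanticConcept:
    """A cluster of n-grams standing for one unit of meaning.

    ``representative`` is the member with the highest document frequency
    (ties broken lexicographically); ``weight`` is assigned later from
    co-mentioning with the core proteins; ``abstract_count`` is the number
    of documents containing any member.
    """

    concept_id: str
    members: frozenset[NGramKey]
    representative: NGramKey
    weight: float | None = None
    abstract_count: int = 0

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")

    @property
    def label(self) -> str:
        return " ".join(self.representative)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def mcl_iterates(
    adjacency: np.ndarray, inflation: float, max_iter: int = 200,
    tol: float = 1e-6, prune: float = 1e-12,
) -> Iterable[np.ndarray]:
    """Yield the column-stochastic matrix after each MCL step.

    Starts from the column-normalized adjacency; each iteration applies
    expansion (matrix square) then inflation (entry-wise power with column
    renormalization).  Iteration stops when the largest entry change falls
    below ``tol`` or after ``max_iter`` rounds.
    """
    m = _column_normalize(adjacency.astype(float))
    yield m
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = _column_normalize(np.power(m, inflation))
        m[m < prune] = 0.0
        m = _column_normalize(m)
        yield m
        if np.max(np.abs(m - prev)) < tol:
            return
    logger.warning("MCL hit the %d-iteration cap; returning current partition",
                   max_iter)


def _clusters_from_matrix(m: np.ndarray) -> list[set[int]]:
    """Hard partition from a converged MCL matrix.

    Each column is attracted to its maximal row (smallest index on ties);
    attractors that retain flow into one another are merged so that an
    attractor system forms a single cluster.
    """
    n = m.shape[0]
    attractor = np.argmax(m, axis=0)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for j in range(n):
        union(j, int(attractor[j]))
    attractors = set(int(a) for a in attractor)
    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > 0.0 or m[b, a] > 0.0):
                union(a, b)
    groups: dict[int, set[int]] = {}
    for j in range(n):
        groups.setdefault(find(j), set()).add(j)
    return [groups[r] for r in sorted(groups)]


def mcl_cluster(
    graph: nx.Graph, inflation: float = 2.0, max_iter: int = 200,
    tol: float = 1e-6,
) -> list[SemanticConcept]:
    """Cluster the similarity graph into semantic concepts with MCL.

    Flow runs on the combined-weight adjacency with self-loops set to each
    node's maximum incident edge weight (1.0 for isolated nodes).  The
    resulting clusters partition the node set; singletons are kept.  Each
    concept is represented by its highest-df member and its id follows the
    deterministic ordering (descending representative df, then
    lexicographic representative).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("similarity graph is empty")
    nodes = sorted(graph.nodes)
    idx = {k: i for i, k in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = data["w_combined"]
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
    for i in range(n):
        incident = adj[i].max()
        adj[i, i] = incident if incident > 0.0 else 1.0
    final = None
    for m in mcl_iterates(adj, inflation, max_iter=max_iter, tol=tol):
        final = m
    concepts = []
    for members_idx in _clusters_from_matrix(final):
        members = frozenset(nodes[i] for i in members_idx)
        rep = min(members, key=lambda k: (-graph.nodes[k].get("df", 0), k))
        postings: set[str] = set()
        for k in members:
            postings |= set(graph.nodes[k].get("postings", ()))
        concepts.append(SemanticConcept(
            concept_id="", members=members, representative=rep,
            abstract_count=len(postings)))
    concepts.sort(key=lambda c: (-c.abstract_count, c.representative))
    for i, c in enumerate(concepts, 1):
        c.concept_id = f"C{i:05d}"
    logger.info("MCL produced %d concepts from %d n-grams", len(concepts), n)
    return concepts
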