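"""Similarity measures and MCL concept clustering."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from litjump import (
    Document,
    build_similarity_graph,
    context_overrepresentation_matrix,
    context_similarity,
    mcl_cluster,
    string_similarity,
)
from litjump.concepts import ContextMatrix, _all_pairs_context_similarity, mcl_iterates
from litjump.ngrams import NGram, NGramCatalog

import scipy.sparse as sp


# --- string similarity ----------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    (("type", "2", "diabetes"), ("diabetes", "type", "ii"), 1.0),
    (("glucose", "homeostasis"), ("glucose", "homeostasis"), 1.0),
    (("glucose", "homeostasis"), ("leptin", "treatment"), 0.0),
    (("glucose", "homeostasis"), ("homeostasis", "glucose"), 1.0),
    (("insulin", "signaling"), ("insulin", "signalling"), 1.0),  # 1 edit
    (("insulin", "receptor"), ("insulin", "receptor", "substrate"), 2 / 3),
    (("ii", "stage"), ("2", "stage"), 1.0),  # roman/arabic aliasing
    (("cat", "dog"), ("car", "dig"), 0.0),   # short tokens need exact match
])
def test_string_similarity_rules(a, b, expected):
    assert string_similarity(a, b) == pytest.approx(expected)
    assert string_similarity(b, a) == pytest.approx(expected)  # symmetric


def test_string_similarity_bounded():
    rng = np.random.default_rng(0)
    words = ["insulin", "receptor", "glucose", "ii", "2", "cat"]
    for _ in range(50):
        a = tuple(rng.choice(words, size=rng.integers(1, 5)))
        b = tuple(rng.choice(words, size=rng.integers(1, 5)))
        s = string_similarity(a, b)
        assert 0.0 <= s <= 1.0


# --- context over-representation matrix -----------------------------------

def _random_catalog(n_ngrams=40, n_docs=60, seed=5):
    rng = np.random.default_rng(seed)
    ngrams = {}
    for i in range(n_ngrams):
        # token pairs kept >= 2 edits apart so no pair is string-similar
        key = (f"t{i:02d}{i:02d}{i:02d}", f"s{i:02d}{i:02d}{i:02d}")
        df = int(rng.integers(2, 15))
        postings = frozenset(str(d) for d in rng.choice(n_docs, df, replace=False))
        ngrams[key] = NGram(tokens=key, postings=postings)
    return NGramCatalog(ngrams=ngrams, D=n_docs)


def test_context_matrix_matches_pairwise_recount():
    cat = _random_catalog()
    ctx = context_overrepresentation_matrix(cat)
    dense = np.asarray(ctx.matrix.todense())
    for i, ki in enumerate(ctx.keys):
        for j, kj in enumerate(ctx.keys):
            co = len(cat[ki].postings & cat[kj].postings)
            expected = co * cat.D / (cat[ki].df * cat[kj].df)
            assert dense[i, j] == pytest.approx(expected, rel=1e-12)
    # diagonal = D / df
    for i, ki in enumerate(ctx.keys):
        assert dense[i, i] == pytest.approx(cat.D / cat[ki].df)


def test_context_matrix_simple_cell():
    ngrams = {
        ("a", "x"): NGram(("a", "x"), frozenset(str(i) for i in range(10))),
        ("b", "y"): NGram(("b", "y"), frozenset(str(i) for i in range(10))),
    }
    cat = NGramCatalog(ngrams=ngrams, D=100)
    ctx = context_overrepresentation_matrix(cat)
    assert ctx.matrix[0, 1] == pytest.approx(10.0)


def _ctx_from_dense(m):
    keys = tuple((f"n{i}",) for i in range(m.shape[0]))
    return ContextMatrix(keys=keys, index={k: i for i, k in enumerate(keys)},
                         matrix=sp.csr_matrix(np.asarray(m, dtype=float)))


def test_context_similarity_identical_rows():
    m = np.array([
        [9, 0, 3, 5, 2],
        [0, 9, 3, 5, 2],
        [3, 3, 9, 0, 0],
        [5, 5, 0, 9, 0],
        [2, 2, 0, 0, 9],
    ], dtype=float)
    ctx = _ctx_from_dense(m)
    # rows 0 and 1 identical outside their own columns
    assert context_similarity(ctx, 0, 1) == pytest.approx(1.0)


def test_context_similarity_orthogonal_rows():
    m = np.array([
        [9, 0, 3, 0],
        [0, 9, 0, 5],
        [3, 0, 9, 0],
        [0, 5, 0, 9],
    ], dtype=float)
    ctx = _ctx_from_dense(m)
    assert context_similarity(ctx, 0, 1) == pytest.approx(0.0)


def test_context_similarity_zero_row_logged():
    m = np.diag([3.0, 3.0, 3.0])
    ctx = _ctx_from_dense(m)
    assert context_similarity(ctx, 0, 1) == 0.0


def test_all_pairs_matches_per_pair(make_corpus):
    cat = _random_catalog(n_ngrams=15)
    ctx = context_overrepresentation_matrix(cat)
    sim = _all_pairs_context_similarity(ctx)
    for i in range(len(ctx.keys)):
        for j in range(i + 1, len(ctx.keys)):
            assert sim[i, j] == pytest.approx(
                context_similarity(ctx, i, j), abs=1e-10)


def test_planted_context_sharers_exceed_threshold(pipeline_run):
    """Two phrases that never co-occur but share partner phrases are context
    similar; phrases from different families are not."""
    run = pipeline_run(0)
    ctx = context_overrepresentation_matrix(run["filtered"])
    sharer = context_similarity(ctx, ("glycemic", "balance"),
                                ("glucose", "homeostasis"))
    cross = context_similarity(ctx, ("glucose", "homeostasis"),
                               ("leptin", "signaling"))
    assert sharer >= 0.5
    assert cross < 0.5
    # and the sharers indeed never co-occur
    cat = run["filtered"]
    assert not (cat[("glycemic", "balance")].postings
                & cat[("glucose", "homeostasis")].postings)


# --- similarity graph ------------------------------------------------------

def test_graph_edge_rule_union_of_thresholds():
    cat = _random_catalog(n_ngrams=10, seed=9)
    g_all = build_similarity_graph(cat, string_threshold=0.0,
                                   context_threshold=0.0)
    g_none = build_similarity_graph(cat, string_threshold=1.0,
                                    context_threshold=1.0)
    n = len(cat)
    assert g_all.number_of_edges() == n * (n - 1) // 2
    # keys are all distinct token pairs => no string similarity 1.0 pairs
    assert g_none.number_of_edges() == 0
    for _u, _v, data in g_all.edges(data=True):
        assert data["w_combined"] == pytest.approx(
            0.5 * data["w_string"] + 0.5 * data["w_context"])


def test_graph_threshold_validation():
    cat = _random_catalog(n_ngrams=4)
    with pytest.raises(ValueError):
        build_similarity_graph(cat, string_threshold=1.5)


# --- MCL -------------------------------------------------------------------

def reference_mcl(adj: np.ndarray, inflation: float, iters: int = 300,
                  tol: float = 1e-8) -> set[frozenset[int]]:
    """Plain textbook MCL, kept independent of the library implementation.

    Expansion = matrix square; inflation = entry-wise power with column
    renormalization; clusters read off the attractor rows of the limit.
    """
    m = adj / adj.sum(axis=0)
    for _ in range(iters):
        prev = m
        m = np.linalg.matrix_power(m, 2)
        m = np.power(m, inflation)
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break
    clusters = []
    for i in range(m.shape[0]):
        if m[i, i] > 1e-6:
            members = frozenset(np.flatnonzero(m[i] > 1e-6).tolist())
            clusters.append(members)
    merged: list[set[int]] = []
    for cl in clusters:
        hit = None
        for g in merged:
            if g & cl:
                hit = g
                break
        if hit is None:
            merged.append(set(cl))
        else:
            hit |= cl
    return {frozenset(g) for g in merged}


def _graph_from_adj(adj):
    g = nx.Graph()
    n = adj.shape[0]
    for i in range(n):
        g.add_node((f"n{i}",), df=1, postings=frozenset({f"d{i}"}))
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] > 0:
                g.add_edge((f"n{i}",), (f"n{j}",), w_string=0.0,
                           w_context=adj[i, j], w_combined=adj[i, j])
    return g


def _partition(concepts):
    return {frozenset(int(k[0][1:]) for k in c.members) for c in concepts}


def test_mcl_two_disconnected_triangles():
    adj = np.zeros((6, 6))
    for tri in ([0, 1, 2], [3, 4, 5]):
        for i in tri:
            for j in tri:
                if i != j:
                    adj[i, j] = 1.0
    concepts = mcl_cluster(_graph_from_adj(adj))
    assert _partition(concepts) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}


def test_mcl_single_node():
    g = nx.Graph()
    g.add_node(("solo",), df=3, postings=frozenset({"d"}))
    concepts = mcl_cluster(g)
    assert len(concepts) == 1
    assert concepts[0].members == frozenset({("solo",)})


def test_mcl_empty_graph_rejected():
    with pytest.raises(ValueError):
        mcl_cluster(nx.Graph())


def _weak_bridge_adjacency(k=5, bridge=0.05):
    """Two k-cliques joined by one weak edge."""
    n = 2 * k
    adj = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for i in block:
            for j in block:
                if i != j:
                    adj[i, j] = 1.0
    adj[k - 1, k] = adj[k, k - 1] = bridge
    return adj


@pytest.mark.parametrize("k,bridge", [(5, 0.05), (5, 1e-3)])
def test_mcl_splits_weakly_joined_cliques(k, bridge):
    adj = _weak_bridge_adjacency(k, bridge)
    concepts = mcl_cluster(_graph_from_adj(adj), inflation=2.0)
    expected = {frozenset(range(k)), frozenset(range(k, 2 * k))}
    assert _partition(concepts) == expected
    # independent reference implementation agrees (self-loops added the
    # same way before both runs)
    with_loops = adj.copy()
    for i in range(2 * k):
        with_loops[i, i] = adj[i].max()
    assert reference_mcl(with_loops, 2.0) == expected


def test_mcl_agrees_with_reference_on_barbell():
    g_nx = nx.barbell_graph(5, 0)  # two 5-cliques sharing one edge
    n = g_nx.number_of_nodes()
    adj = nx.to_numpy_array(g_nx)
    concepts = mcl_cluster(_graph_from_adj(adj), inflation=2.0)
    with_loops = adj.copy()
    for i in range(n):
        with_loops[i, i] = adj[i].max()
    assert _partition(concepts) == reference_mcl(with_loops, 2.0)


def test_mcl_column_stochastic_invariant():
    adj = _weak_bridge_adjacency()
    for i in range(adj.shape[0]):
        adj[i, i] = adj[i].max()
    for m in mcl_iterates(adj, inflation=2.0):
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)


def _fixture_graphs():
    yield _weak_bridge_adjacency(5, 0.05)
    yield _weak_bridge_adjacency(4, 0.2)
    yield nx.to_numpy_array(nx.barbell_graph(5, 0))
    yield nx.to_numpy_array(nx.karate_club_graph())
    rng = np.random.default_rng(2)
    a = rng.random((12, 12)) * (rng.random((12, 12)) < 0.3)
    yield (a + a.T) / 2


def test_inflation_monotone_cluster_count():
    for adj in _fixture_graphs():
        counts = [len(mcl_cluster(_graph_from_adj(adj), inflation=r))
                  for r in (1.5, 2.0, 4.0)]
        assert counts == sorted(counts)


def test_mcl_clusters_partition_nodes(pipeline_run):
    run = pipeline_run(0)
    concepts = run["concepts"]
    seen: set = set()
    for c in concepts:
        assert not (c.members & seen)
        seen |= c.members
        assert c.representative in c.members
    assert seen == set(run["filtered"].keys())


def test_representative_is_most_frequent_member(pipeline_run):
    run = pipeline_run(0)
    cat = run["filtered"]
    for c in run["concepts"]:
        max_df = max(cat[m].df for m in c.members)
        assert cat[c.representative].df == max_df


def test_family_recovery_single_seed(pipeline_run):
    from sklearn.metrics import adjusted_rand_score
    run = pipeline_run(0)
    gt = run["truth"]
    member_of = {}
    for idx, c in enumerate(run["concepts"]):
        for m in c.members:
            member_of[m] = idx
    keys, true_labels, found_labels = [], [], []
    for fam_idx, (name, fam_keys) in enumerate(sorted(gt.families.items())):
        for k in fam_keys:
            keys.append(k)
            true_labels.append(fam_idx)
            found_labels.append(member_of[k])
    assert adjusted_rand_score(true_labels, found_labels) >= 0.9
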