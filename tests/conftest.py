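"""Shared fixtures: synthetic corpora and cached full-pipeline runs."""

from __future__ import annotations

from functools import lru_cache

import pytest

from litjump import (
    GeneratorConfig,
    build_similarity_graph,
    disease_overrepresented,
    extract_ngrams,
    generate_corpus,
    mcl_cluster,
    relevance_timeline,
    score_articles,
    select_core_proteins,
    weight_concepts,
)
from litjump.scoring import weekly_scores_by_week


@lru_cache(maxsize=32)
def _corpus(seed: int):
    cfg = GeneratorConfig(seed=seed)
    docs, gt = generate_corpus(cfg)
    return cfg, docs, gt


@lru_cache(maxsize=32)
def _full_run(seed: int):
    """Run every pipeline stage in memory on the default synthetic corpus."""
    cfg, docs, gt = _corpus(seed)
    protein_ids = {p.protein_id for p in cfg.proteins}
    core = select_core_proteins(
        docs, protein_ids, cfg.disease_id, K=len(gt.core_proteins))
    catalog = extract_ngrams(docs)
    disease_docs = [d.doc_id for d in docs
                    if cfg.disease_id in {e for e, _ in d.mentions}]
    filtered = disease_overrepresented(catalog, disease_docs)
    graph = build_similarity_graph(filtered)
    concepts = weight_concepts(
        mcl_cluster(graph), core, docs, filtered)
    scores = score_articles(docs, concepts)
    weekly = weekly_scores_by_week(docs, scores)
    weeks = sorted({d.week for d in docs})
    series = relevance_timeline(weekly, sorted(protein_ids), weeks,
                                W=260, M=40)
    hist = {w: {p: series[p].rank[w] for p in protein_ids} for w in weeks}
    return {
        "config": cfg, "docs": docs, "truth": gt, "core": core,
        "catalog": catalog, "filtered": filtered, "graph": graph,
        "concepts": concepts, "scores": scores, "weekly": weekly,
        "series": series, "rank_history": hist, "weeks": weeks,
    }


@pytest.fixture(scope="session")
def make_corpus():
    """Factory fixture: seeded default synthetic corpus (cached)."""
    return _corpus


@pytest.fixture(scope="session")
def pipeline_run():
    """Factory fixture: full in-memory pipeline run for a seed (cached)."""
    return _full_run
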