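"""Staged pipeline: configuration, cached intermediates and reports.

The method is weekly and incremental by design, so the pipeline is staged
with on-disk, tab-separated intermediates: each stage reads the artifacts of
the previous one, is idempotent for identical inputs and configuration, and
logs the funnel counts (documents skipped, n-grams dropped, concepts
formed).  A serialized copy of the configuration is written next to the
outputs for provenance, and stages are cached on a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import association, concepts as concepts_mod, corpus as corpus_mod
from . import jumps as jumps_mod, ngrams as ngrams_mod, scoring, synthetic
from .association import CoreProteinSet
from .concepts import SemanticConcept
from .corpus import Document, EntityDictionary
from .ngrams import NGram, NGramCatalog, NGramKey

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "ingest", "core-proteins", "mine-ngrams", "cluster-concepts",
    "weight-concepts", "score-articles", "score-proteins", "detect-jumps",
    "evaluate-roc",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the method's default settings."""

    workdir: str = "litjump_out"
    corpus_path: str | None = None
    corpus_format: str = "records_jsonl"
    protein_dict_path: str | None = None
    disease_dict_path: str | None = None
    disease_id: str = "T2D"
    K: int = 100
    n_range: tuple[int, int] = (2, 6)
    min_df: int = 5
    min_co: int = 3
    min_ratio: float = 2.0
    filter_alpha: float = 0.01
    string_threshold: float = 0.8
    context_threshold: float = 0.5
    lam: float = 0.5
    inflation: float = 2.0
    W: int = 260
    M: int = 40
    top_m_weighting: str = "linear"  # the only implemented scheme; see docs
    jump_alpha: float = 0.05
    multiple_testing: str = "none"  # weekly jump p-values are not corrected
    roc_positives_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        lo, hi = self.n_range
        if not 1 <= lo <= hi <= 8:
            raise ValueError("n_range must satisfy 1 <= lo <= hi <= 8")
        if self.W < self.M:
            raise ValueError("window W must be >= M")
        if self.top_m_weighting != "linear":
            raise ValueError("only the linear top-M weighting is implemented")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_range" in data:
            data["n_range"] = tuple(data["n_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        rec = dataclasses.asdict(self)
        rec["n_range"] = list(self.n_range)
        Path(path).write_text(yaml.safe_dump(rec, sort_keys=True), encoding="utf-8")

    def digest(self) -> str:
        rec = dataclasses.asdict(self)
        rec["n_range"] = list(self.n_range)
        return hashlib.sha256(
            json.dumps(rec, sort_keys=True).encode()).hexdigest()[:16]


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not been run yet."""


# ---------------------------------------------------------------------------
# artifact serialization (all TSV/JSONL so every report row is re-derivable)

def _workdir(cfg: PipelineConfig) -> Path:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the {produced_by!r} stage first")
    return path


def _write_catalog(catalog: NGramCatalog, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#D={catalog.D}\tdisease_df={catalog.disease_df}\n")
        fh.write("ngram\tdf\tratio\tp_value\tpostings\n")
        for key in sorted(catalog.keys()):
            ng = catalog[key]
            fh.write("{}\t{}\t{:.6g}\t{:.6g}\t{}\n".format(
                " ".join(key), ng.df,
                catalog.ratios.get(key, float("nan")),
                catalog.pvalues.get(key, float("nan")),
                ",".join(sorted(ng.postings))))


def _read_catalog(path: Path) -> NGramCatalog:
    ngrams: dict[NGramKey, NGram] = {}
    ratios: dict[NGramKey, float] = {}
    pvalues: dict[NGramKey, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().lstrip("#")
        meta = dict(kv.split("=") for kv in header.split("\t"))
        fh.readline()  # column header
        for line in fh:
            text, _df, ratio, p, postings = line.rstrip("\n").split("\t")
            key = tuple(text.split(" "))
            ngrams[key] = NGram(tokens=key,
                                postings=frozenset(postings.split(",")))
            ratios[key] = float(ratio)
            pvalues[key] = float(p)
    return NGramCatalog(ngrams=ngrams, D=int(meta["D"]),
                        disease_df=int(meta["disease_df"]),
                        ratios=ratios, pvalues=pvalues)


def _write_concepts(concepts: Sequence[SemanticConcept], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("concept_id\trepresentative\tweight\tabstract_count\tmembers\n")
        for c in concepts:
            w = "" if c.weight is None else f"{c.weight:.6g}"
            fh.write("{}\t{}\t{}\t{}\t{}\n".format(
                c.concept_id, " ".join(c.representative), w, c.abstract_count,
                "|".join(" ".join(m) for m in sorted(c.members))))


def _read_concepts(path: Path) -> list[SemanticConcept]:
    out: list[SemanticConcept] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            cid, rep, w, count, members = line.rstrip("\n").split("\t")
            out.append(SemanticConcept(
                concept_id=cid,
                members=frozenset(tuple(m.split(" ")) for m in members.split("|")),
                representative=tuple(rep.split(" ")),
                weight=float(w) if w else None,
                abstract_count=int(count)))
    return out


def _load_docs(cfg: PipelineConfig) -> list[Document]:
    path = _require(_workdir(cfg) / "corpus.jsonl", "ingest")
    return corpus_mod.read_corpus(path, "records_jsonl")


def _load_core(cfg: PipelineConfig) -> CoreProteinSet:
    path = _require(_workdir(cfg) / "core_proteins.tsv", "core-proteins")
    rows = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[1], float(parts[6])))
    return CoreProteinSet(proteins=tuple(rows), K=max(cfg.K, len(rows)))


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig) -> None:
    gen = synthetic.GeneratorConfig(seed=cfg.seed)
    docs, gt = synthetic.generate_corpus(gen)
    wd = _workdir(cfg)
    corpus_mod.write_corpus_jsonl(docs, wd / "corpus.jsonl")
    gt.to_json(wd / "ground_truth.json")
    gen.dictionary().to_tsv(wd / "dictionary.tsv")


def _stage_ingest(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    if cfg.corpus_path is None:
        _require(wd / "corpus.jsonl", "simulate")
        return
    docs = corpus_mod.read_corpus(cfg.corpus_path, cfg.corpus_format)
    dicts = []
    for p in (cfg.protein_dict_path, cfg.disease_dict_path):
        if p:
            dicts.append(EntityDictionary.from_tsv(p))
    if dicts:
        docs = corpus_mod.annotate(docs, *dicts)
    corpus_mod.write_corpus_jsonl(docs, wd / "corpus.jsonl")


def _stage_core_proteins(cfg: PipelineConfig) -> None:
    docs = _load_docs(cfg)
    proteins = {eid for d in docs for eid, cls in d.mentions
                if cls == corpus_mod.PROTEIN}
    core = association.select_core_proteins(
        docs, proteins, cfg.disease_id, K=cfg.K)
    association.write_core_proteins_tsv(
        docs, core, cfg.disease_id, _workdir(cfg) / "core_proteins.tsv")


def _stage_mine_ngrams(cfg: PipelineConfig) -> None:
    docs = _load_docs(cfg)
    catalog = ngrams_mod.extract_ngrams(
        docs, n_range=cfg.n_range, min_df=cfg.min_df)
    disease_docs = [d.doc_id for d in docs
                    if cfg.disease_id in {e for e, _ in d.mentions}]
    filtered = ngrams_mod.disease_overrepresented(
        catalog, disease_docs, min_co=cfg.min_co, min_ratio=cfg.min_ratio,
        alpha=cfg.filter_alpha)
    _write_catalog(filtered, _workdir(cfg) / "ngrams.tsv")


def _stage_cluster_concepts(cfg: PipelineConfig) -> None:
    catalog = _read_catalog(_require(_workdir(cfg) / "ngrams.tsv", "mine-ngrams"))
    graph = concepts_mod.build_similarity_graph(
        catalog, string_threshold=cfg.string_threshold,
        context_threshold=cfg.context_threshold, lam=cfg.lam)
    clusters = concepts_mod.mcl_cluster(graph, inflation=cfg.inflation)
    _write_concepts(clusters, _workdir(cfg) / "concepts.tsv")


def _stage_weight_concepts(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    docs = _load_docs(cfg)
    catalog = _read_catalog(_require(wd / "ngrams.tsv", "mine-ngrams"))
    clusters = _read_concepts(_require(wd / "concepts.tsv", "cluster-concepts"))
    core = _load_core(cfg)
    weighted = scoring.weight_concepts(clusters, core, docs, catalog)
    weighted.sort(key=lambda c: (-(c.weight or 0.0), c.representative))
    _write_concepts(weighted, wd / "concepts.tsv")


def _stage_score_articles(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    docs = _load_docs(cfg)
    clusters = _read_concepts(_require(wd / "concepts.tsv", "cluster-concepts"))
    if any(c.weight is None for c in clusters):
        raise MissingArtifactError(
            "concepts have no weights; run the 'weight-concepts' stage first")
    scores = scoring.score_articles(docs, clusters)
    with open(wd / "article_scores.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tweek\tscore\tcontributions\n")
        for doc in docs:
            s = scores[doc.doc_id]
            contr = ";".join(f"{cid}:{w:.6g}" for cid, w in s.contributions)
            fh.write(f"{doc.doc_id}\t{doc.week}\t{s.score:.6g}\t{contr}\n")


def _read_article_scores(cfg: PipelineConfig) -> dict[str, scoring.ArticleScore]:
    path = _require(_workdir(cfg) / "article_scores.tsv", "score-articles")
    out: dict[str, scoring.ArticleScore] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            doc_id, _week, score, contr = line.rstrip("\n").split("\t")
            contributions = tuple(
                (cid, float(w)) for cid, w in
                (c.split(":") for c in contr.split(";") if c))
            out[doc_id] = scoring.ArticleScore(
                doc_id=doc_id, score=float(score), contributions=contributions)
    return out


def _stage_score_proteins(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    docs = _load_docs(cfg)
    scores = _read_article_scores(cfg)
    weekly = scoring.weekly_scores_by_week(docs, scores)
    proteins = sorted({eid for d in docs for eid, cls in d.mentions
                       if cls == corpus_mod.PROTEIN})
    weeks = sorted({d.week for d in docs})
    series = scoring.relevance_timeline(weekly, proteins, weeks,
                                        W=cfg.W, M=cfg.M)
    with open(wd / "protein_ranks.tsv", "w", encoding="utf-8") as fh:
        fh.write("week\tprotein_id\tweekly_score\tcombined\trank\n")
        for w in weeks:
            for pid in proteins:
                s = series[pid]
                fh.write("{}\t{}\t{:.6g}\t{:.6g}\t{}\n".format(
                    w, pid, s.weekly_scores.get(w, 0.0), s.combined[w],
                    s.rank[w]))


def _read_rank_history(cfg: PipelineConfig) -> dict[int, dict[str, int]]:
    path = _require(_workdir(cfg) / "protein_ranks.tsv", "score-proteins")
    hist: dict[int, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            w, pid, _ws, _comb, rank = line.rstrip("\n").split("\t")
            hist.setdefault(int(w), {})[pid] = int(rank)
    return hist


def _stage_detect_jumps(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    docs = _load_docs(cfg)
    scores = _read_article_scores(cfg)
    hist = _read_rank_history(cfg)
    weeks = sorted(hist)
    docs_by_week: dict[int, list[Document]] = {}
    for d in docs:
        docs_by_week.setdefault(d.week, []).append(d)
    with open(wd / "high_jumpers.tsv", "w", encoding="utf-8") as fh:
        fh.write("week\tprotein_id\tinitial_rank\tnew_rank\tjump\tp_value\t"
                 "trigger_doc_id\ttop_concepts\n")
        for prev_w, w in zip(weeks[:-1], weeks[1:]):
            if weeks.index(w) < 2:
                continue  # need history before the first evaluation
            try:
                dist = jumps_mod.build_jump_distribution(hist, upto_week=w)
            except ValueError:
                continue
            triggers: dict[str, str] = {}
            for d in docs_by_week.get(w, []):
                for pid in d.entities(corpus_mod.PROTEIN):
                    cur = triggers.get(pid)
                    if cur is None or scores[d.doc_id].score > scores[cur].score:
                        triggers[pid] = d.doc_id
            found = jumps_mod.weekly_high_jumpers(
                hist[prev_w], hist[w], dist, alpha=cfg.jump_alpha,
                trigger_docs=triggers)
            for h in found:
                top = ""
                if h.trigger_doc_id:
                    top = ";".join(
                        f"{cid}:{wt:.4g}" for cid, wt in
                        scores[h.trigger_doc_id].contributions[:5])
                fh.write(f"{w}\t{h.protein_id}\t{h.initial_rank}\t{h.new_rank}"
                         f"\t{h.jump}\t{h.p_value:.6g}\t"
                         f"{h.trigger_doc_id or ''}\t{top}\n")


def _stage_evaluate_roc(cfg: PipelineConfig) -> None:
    wd = _workdir(cfg)
    hist_path = _require(wd / "protein_ranks.tsv", "score-proteins")
    combined: dict[str, float] = {}
    last_week = None
    with open(hist_path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            w, pid, _ws, comb, _rank = line.rstrip("\n").split("\t")
            w = int(w)
            if last_week is None or w > last_week:
                last_week = w
    with open(hist_path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            w, pid, _ws, comb, _rank = line.rstrip("\n").split("\t")
            if int(w) == last_week:
                combined[pid] = float(comb)
    if cfg.roc_positives_path:
        positives = {
            line.strip() for line in
            Path(cfg.roc_positives_path).read_text(encoding="utf-8").splitlines()
            if line.strip()}
    else:
        gt_path = _require(wd / "ground_truth.json", "simulate")
        positives = set(synthetic.GroundTruth.from_json(gt_path).core_proteins)
    auc, points = scoring.evaluate_roc(combined, positives)
    with open(wd / "roc.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"#auc={auc:.6g}\n")
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ingest": _stage_ingest,
    "core-proteins": _stage_core_proteins,
    "mine-ngrams": _stage_mine_ngrams,
    "cluster-concepts": _stage_cluster_concepts,
    "weight-concepts": _stage_weight_concepts,
    "score-articles": _stage_score_articles,
    "score-proteins": _stage_score_proteins,
    "detect-jumps": _stage_detect_jumps,
    "evaluate-roc": _stage_evaluate_roc,
}

_STAGE_OUTPUTS = {
    "simulate": ("corpus.jsonl", "ground_truth.json", "dictionary.tsv"),
    "ingest": ("corpus.jsonl",),
    "core-proteins": ("core_proteins.tsv",),
    "mine-ngrams": ("ngrams.tsv",),
    "cluster-concepts": ("concepts.tsv",),
    "weight-concepts": ("concepts.tsv",),
    "score-articles": ("article_scores.tsv",),
    "score-proteins": ("protein_ranks.tsv",),
    "detect-jumps": ("high_jumpers.tsv",),
    "evaluate-roc": ("roc.tsv",),
}


def run_stage(stage: str, cfg: PipelineConfig, force: bool = False) -> None:
    """Run one pipeline stage, reusing cached output when the configuration
    hash matches a previous run."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    cfg.validate()
    wd = _workdir(cfg)
    cache_path = wd / ".stage_hashes.json"
    cache = json.loads(cache_path.read_text()) if cache_path.exists() else {}
    digest = cfg.digest()
    outputs = [wd / name for name in _STAGE_OUTPUTS[stage]]
    if (not force and cache.get(stage) == digest
            and all(p.exists() for p in outputs)):
        logger.info("stage %s: cached (config %s)", stage, digest)
        return
    logger.info("stage %s: running", stage)
    _STAGE_FUNCS[stage](cfg)
    cfg.to_yaml(wd / "config.used.yaml")
    cache[stage] = digest
    cache_path.write_text(json.dumps(cache, indent=1))


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] | None = None) -> None:
    order = [s for s in STAGES if s != "simulate" or cfg.corpus_path is None]
    for stage in (stages or order):
        run_stage(stage, cfg)


@dataclass(frozen=True)
class ArticleExplanation:
    doc_id: str
    score: float
    contributions: tuple[tuple[str, str, tuple[str, ...], float], ...]
    # (concept_id, representative, matched member n-grams, weight)


def explain_article(doc_id: str, cfg: PipelineConfig) -> ArticleExplanation:
    """Break an article's score into its concepts and matched n-grams.

    The per-concept lines sum exactly to the stored article score, giving
    the markup-style explanation of why the article ranked where it did.
    """
    wd = _workdir(cfg)
    docs = {d.doc_id: d for d in _load_docs(cfg)}
    if doc_id not in docs:
        raise KeyError(f"unknown document {doc_id!r}")
    clusters = _read_concepts(_require(wd / "concepts.tsv", "cluster-concepts"))
    scores = _read_article_scores(cfg)
    doc = docs[doc_id]
    windows = {tuple(doc.tokens[i:i + n])
               for n in range(1, 9) for i in range(len(doc.tokens) - n + 1)}
    by_id = {c.concept_id: c for c in clusters}
    contribs = []
    for cid, weight in scores[doc_id].contributions:
        c = by_id[cid]
        matched = tuple(sorted(" ".join(m) for m in c.members if m in windows))
        contribs.append((cid, " ".join(c.representative), matched, weight))
    return ArticleExplanation(
        doc_id=doc_id, score=scores[doc_id].score,
        contributions=tuple(contribs))
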