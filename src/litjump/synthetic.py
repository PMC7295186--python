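"""Seeded synthetic corpora with planted, recoverable structure.

The generator emulates the statistical skeleton of a weekly abstract stream:

* filler tokens drawn from a fixed vocabulary (no attempt at real English);
* latent *phrase families* — groups of multi-word phrases consisting of a
  canonical phrase, string variants (word-order permutations, one-letter
  misspellings, roman/arabic numeral aliases), and a *context member* that
  never co-occurs with the other members but shares their partner phrases
  (the two mechanisms that concept clustering must absorb);
* protein mentions with controlled disease co-mention rates, so Fisher
  ranking has planted "core" proteins to recover;
* one *jumper* protein that appears at a chosen week inside a single
  document loaded with high-affinity phrases, producing a significant rank
  jump.

Every pipeline stage can therefore be tested against exact ground truth,
and each seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import DISEASE, PROTEIN, Document, EntityDictionary
from .ngrams import NGramKey

__all__ = [
    "PhraseFamily", "ProteinSpec", "JumperSpec", "GeneratorConfig",
    "GroundTruth", "generate_corpus", "ground_truth", "default_families",
    "default_proteins",
]


@dataclass(frozen=True)
class PhraseFamily:
    """One latent semantic concept planted in the corpus.

    ``members`` are string-similar variants of one phrase; the optional
    ``context_member`` is a textually unrelated phrase inserted in the same
    documents as the partners but never together with the other members.
    ``partners`` co-occur with every member and act as the shared context.
    """

    name: str
    members: tuple[NGramKey, ...]
    context_member: NGramKey | None
    partners: tuple[NGramKey, ...]

    def concept_keys(self) -> frozenset[NGramKey]:
        keys = set(self.members)
        if self.context_member is not None:
            keys.add(self.context_member)
        return frozenset(keys)


@dataclass(frozen=True)
class ProteinSpec:
    """Mention rates for one protein in disease-topic vs background docs."""

    protein_id: str
    disease_doc_rate: float
    background_doc_rate: float


@dataclass(frozen=True)
class JumperSpec:
    """The planted jump: protein, week, and how many phrase families are
    packed into the triggering document."""

    protein_id: str
    week: int
    n_families: int = 4


def default_families() -> tuple[PhraseFamily, ...]:
    """Five phrase families exercising every variant mechanism."""
    return (
        PhraseFamily(
            "glucose_homeostasis",
            members=(("glucose", "homeostasis"),
                     ("homeostasis", "glucose"),
                     ("glucose", "homeostasys")),
            context_member=("glycemic", "balance"),
            partners=(("islet", "function"), ("beta", "cell", "mass"))),
        PhraseFamily(
            "insulin_resistance",
            members=(("insulin", "resistance"),
                     ("resistance", "insulin"),
                     ("insulin", "resistence")),
            context_member=("metabolic", "dysfunction"),
            partners=(("adipose", "tissue"), ("fatty", "liver"))),
        PhraseFamily(
            "leptin_signaling",
            members=(("leptin", "signaling"),
                     ("signaling", "leptin"),
                     ("leptin", "signalling")),
            context_member=("appetite", "regulation"),
            partners=(("hypothalamic", "neurons"), ("energy", "expenditure"))),
        PhraseFamily(
            "lipid_metabolism",
            members=(("lipid", "metabolism"),
                     ("metabolism", "lipid"),
                     ("lipid", "metabolizm")),
            context_member=("triglyceride", "clearance"),
            partners=(("lipoprotein", "lipase"), ("hepatic", "steatosis"))),
        PhraseFamily(
            "diabetes_type_2",
            members=(("diabetes", "type", "2"),
                     ("type", "2", "diabetes"),
                     ("diabetes", "type", "ii")),
            context_member=("chronic", "hyperglycemia"),
            partners=(("oral", "challenge"), ("fasting", "plasma"))),
    )


def default_proteins(
    n_linked: int = 10, n_background: int = 40, n_tail: int = 100,
    linked_rate: float = 0.12, star_rate: float = 0.6,
    background_disease_rate: float = 0.01,
    background_rate: float = 0.02,
) -> tuple[ProteinSpec, ...]:
    """Protein universe with the rank structure of a real corpus.

    One highly mentioned "star" and the disease-linked proteins (the
    planted core set) occupy the top ranks; weakly topic-mentioned
    background proteins churn in the mid-field; and a long tail of proteins
    mentioned only in non-topic documents scores zero and sits in static
    ranks — the stratum real jumpers emerge from.
    """
    specs = [ProteinSpec("dp00", star_rate, 0.005)]
    specs += [ProteinSpec(f"dp{i:02d}", linked_rate, 0.005)
              for i in range(1, n_linked)]
    specs += [ProteinSpec(f"bp{i:02d}", background_disease_rate, background_rate)
              for i in range(n_background)]
    specs += [ProteinSpec(f"tp{i:02d}", 0.0, background_rate)
              for i in range(n_tail)]
    return tuple(specs)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic corpus; the seed fixes every draw."""

    n_weeks: int = 60
    docs_per_week: int = 50
    vocabulary_size: int = 500
    phrase_families: tuple[PhraseFamily, ...] = field(default_factory=default_families)
    proteins: tuple[ProteinSpec, ...] = field(default_factory=default_proteins)
    disease_id: str = "T2D"
    disease_synonym: str = "t2d"
    p_disease_topic: float = 0.3
    disease_rate_topic: float = 0.6
    disease_rate_background: float = 0.02
    p_context_member: float = 0.3
    filler_len: tuple[int, int] = (15, 30)
    jumper: JumperSpec | None = field(default_factory=lambda: JumperSpec("tp50", 50, 4))
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("p_disease_topic", "disease_rate_topic",
                     "disease_rate_background", "p_context_member"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        for sp in self.proteins:
            if not (0.0 <= sp.disease_doc_rate <= 1.0
                    and 0.0 <= sp.background_doc_rate <= 1.0):
                bad.append(f"proteins[{sp.protein_id}]")
        if self.n_weeks < 1:
            bad.append("n_weeks")
        if self.docs_per_week < 1:
            bad.append("docs_per_week")
        if self.vocabulary_size < 10:
            bad.append("vocabulary_size")
        if self.jumper is not None:
            if not 0 <= self.jumper.week < self.n_weeks:
                bad.append("jumper.week")
            if self.jumper.protein_id not in {p.protein_id for p in self.proteins}:
                bad.append("jumper.protein_id")
        if bad:
            raise ValueError(f"invalid generator config fields: {', '.join(bad)}")

    def dictionary(self) -> EntityDictionary:
        """Entity dictionary matching the generated mentions: each protein's
        synonym is its lowercased id; the disease has one synonym."""
        d = EntityDictionary()
        for sp in self.proteins:
            d.add(sp.protein_id.lower(), sp.protein_id, PROTEIN)
        d.add(self.disease_synonym, self.disease_id, DISEASE)
        return d


@dataclass
class GroundTruth:
    """The planted structure recovery tests assert against.

    ``families`` maps a family name to the n-gram keys planted as one
    semantic concept (the string variants plus the context member).
    Partner phrases are scaffolding — they provide the shared context — and
    are deliberately not part of any family: clustering may leave them
    alone or attach them to the family they serve, and neither outcome is
    wrong, so recovery is judged on the family keys only.
    """

    families: dict[str, frozenset[NGramKey]]
    core_proteins: frozenset[str]
    star_protein: str
    jumper: JumperSpec | None
    disease_id: str

    def planted_keys(self) -> frozenset[NGramKey]:
        out: set[NGramKey] = set()
        for keys in self.families.values():
            out |= keys
        return frozenset(out)

    def to_json(self, path: str | Path) -> None:
        rec = {
            "families": {name: sorted(list(k) for k in keys)
                         for name, keys in self.families.items()},
            "core_proteins": sorted(self.core_proteins),
            "star_protein": self.star_protein,
            "jumper": asdict(self.jumper) if self.jumper else None,
            "disease_id": self.disease_id,
        }
        Path(path).write_text(json.dumps(rec, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        rec = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            families={name: frozenset(tuple(k) for k in keys)
                      for name, keys in rec["families"].items()},
            core_proteins=frozenset(rec["core_proteins"]),
            star_protein=rec["star_protein"],
            jumper=JumperSpec(**rec["jumper"]) if rec["jumper"] else None,
            disease_id=rec["disease_id"],
        )


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """The planted structure implied by a config (no sampling involved)."""
    config.validate()
    families: dict[str, frozenset[NGramKey]] = {}
    for fam in config.phrase_families:
        families[fam.name] = fam.concept_keys()
    linked = frozenset(
        sp.protein_id for sp in config.proteins
        if sp.disease_doc_rate >= 10 * max(sp.background_doc_rate, 1e-9))
    star = max(config.proteins, key=lambda sp: sp.disease_doc_rate).protein_id
    return GroundTruth(families=families, core_proteins=linked,
                       star_protein=star, jumper=config.jumper,
                       disease_id=config.disease_id)


def _assemble(rng: np.random.Generator, filler: list[str],
              items: list[list[str]]) -> list[str]:
    """Insert token groups contiguously at distinct, non-adjacent slots."""
    if not items:
        return filler
    slots = sorted(rng.choice(len(filler) + 1, size=len(items), replace=False))
    out: list[str] = []
    prev = 0
    for slot, item in zip(slots, items):
        out.extend(filler[prev:slot])
        out.extend(item)
        prev = slot
    out.extend(filler[prev:])
    return out


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Document], GroundTruth]:
    """Sample the weekly document stream described by ``config``.

    Each document is either a disease-topic document (one phrase-family
    member or the family's context member, plus partner phrases, disease
    term and protein mentions at their topic rates) or a background
    document of filler.  The jumper protein's triggering document is packed
    with members and partners from several families.  Fully reproducible
    for a given seed.
    """
    config.validate()
    gt = ground_truth(config)
    rng = np.random.default_rng(config.seed)
    vocab = [f"w{i:03d}" for i in range(config.vocabulary_size)]
    docs: list[Document] = []
    lo, hi = config.filler_len
    families = config.phrase_families
    for week in range(config.n_weeks):
        for i in range(config.docs_per_week):
            doc_id = f"d{week:03d}_{i:03d}"
            filler = [vocab[k] for k in rng.integers(0, len(vocab), size=rng.integers(lo, hi + 1))]
            items: list[list[str]] = []
            mentions: set[tuple[str, str]] = set()
            is_topic = bool(families) and rng.random() < config.p_disease_topic
            if is_topic:
                fam = families[rng.integers(0, len(families))]
                if fam.context_member is not None and rng.random() < config.p_context_member:
                    items.append(list(fam.context_member))
                else:
                    m = fam.members[rng.integers(0, len(fam.members))]
                    items.append(list(m))
                n_partners = 1 + int(rng.random() < 0.5)
                for j in rng.choice(len(fam.partners),
                                    size=min(n_partners, len(fam.partners)),
                                    replace=False):
                    items.append(list(fam.partners[j]))
                disease_rate = config.disease_rate_topic
            else:
                disease_rate = config.disease_rate_background
            if rng.random() < disease_rate:
                items.append([config.disease_synonym])
                mentions.add((config.disease_id, DISEASE))
            for sp in config.proteins:
                rate = sp.disease_doc_rate if is_topic else sp.background_doc_rate
                if (config.jumper is not None
                        and sp.protein_id == config.jumper.protein_id
                        and is_topic):
                    # the jumper is quiescent: no disease-topic mentions
                    # outside its planted triggering document, mirroring a
                    # protein first linked to the disease by a single article
                    rate = 0.0
                if rng.random() < rate:
                    items.append([sp.protein_id.lower()])
                    mentions.add((sp.protein_id, PROTEIN))
            tokens = _assemble(rng, filler, items)
            docs.append(Document(doc_id=doc_id, week=week,
                                 tokens=tuple(tokens),
                                 mentions=frozenset(mentions)))
    if config.jumper is not None and families:
        jp = config.jumper
        filler = [vocab[k] for k in rng.integers(0, len(vocab), size=hi)]
        items = []
        for fam in families[:jp.n_families]:
            items.append(list(fam.members[0]))
            items.append(list(fam.partners[0]))
        items.append([jp.protein_id.lower()])
        tokens = _assemble(rng, filler, items)
        docs.append(Document(
            doc_id=f"jump_{jp.protein_id}_{jp.week:03d}", week=jp.week,
            tokens=tuple(tokens),
            mentions=frozenset({(jp.protein_id, PROTEIN)})))
        docs.sort(key=lambda d: (d.week, d.doc_id))
    return docs, gt
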