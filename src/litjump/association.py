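"""Protein–disease co-mention statistics and core-protein selection.

Each protein's association with the disease is measured by a one-sided
Fisher's exact test on the 2x2 table of document-level co-mentioning; the K
proteins with the smallest p-values form the "core" set that anchors concept
weighting downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import fisher_exact as _scipy_fisher

from .corpus import DISEASE, PROTEIN, Document, EntityDictionary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Document counts for two entities: both, A only, B only, neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CoreProteinSet:
    """The K proteins most significantly co-mentioned with the disease.

    ``proteins`` is ordered by ascending p-value (ties broken by ascending
    protein id).
    """

    proteins: tuple[tuple[str, float], ...]
    K: int

    def __post_init__(self) -> None:
        if len(self.proteins) > self.K:
            raise ValueError("core set longer than K")
        ps = [p for _, p in self.proteins]
        if any(ps[i] > ps[i + 1] for i in range(len(ps) - 1)):
            raise ValueError("core set p-values must be non-decreasing")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)


def comention_table(
    docs: Sequence[Document], a_id: str, b_id: str
) -> ContingencyTable2x2:
    """Count documents by presence/absence of entities A and B."""
    if not docs:
        raise ValueError("document sequence is empty")
    a = b = c = d = 0
    for doc in docs:
        ids = {eid for eid, _cls in doc.mentions}
        has_a, has_b = a_id in ids, b_id in ids
        if has_a and has_b:
            a += 1
        elif has_a:
            b += 1
        elif has_b:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_p(table: ContingencyTable2x2, side: str = "greater") -> float:
    """Exact hypergeometric tail probability for a 2x2 table.

    ``side='greater'`` tests over-co-mentioning (the default: positive
    association is what makes a protein "core").  Degenerate margins
    (no document mentions one of the entities) give p = 1 by convention.
    """
    if side not in ("greater", "two_sided"):
        raise ValueError(f"unknown side {side!r}")
    if table.a + table.b == 0 or table.a + table.c == 0:
        logger.debug("degenerate margin in %s; p=1 by convention", table)
        return 1.0
    alternative = "greater" if side == "greater" else "two-sided"
    res = _scipy_fisher([[table.a, table.b], [table.c, table.d]],
                        alternative=alternative)
    return float(res.pvalue)


def select_core_proteins(
    docs: Sequence[Document],
    protein_ids: Iterable[str] | EntityDictionary,
    disease_id: str,
    K: int = 100,
    side: str = "greater",
) -> CoreProteinSet:
    """Rank proteins by Fisher p-value against the disease and keep the top K.

    Only proteins actually mentioned in ``docs`` are candidates.  Ties are
    broken by ascending protein id so the ranking is reproducible.  If fewer
    than K proteins are mentioned, all of them are returned with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(protein_ids, EntityDictionary):
        candidates = protein_ids.entity_ids(PROTEIN)
    else:
        candidates = set(protein_ids)
    mentioned = set()
    for doc in docs:
        mentioned |= {eid for eid, cls in doc.mentions if cls == PROTEIN}
    candidates &= mentioned
    if len(candidates) < K:
        logger.warning(
            "only %d proteins mentioned in corpus; returning all (K=%d)",
            len(candidates), K)
    scored = []
    for pid in sorted(candidates):
        p = fisher_exact_p(comention_table(docs, pid, disease_id), side=side)
        scored.append((pid, p))
    scored.sort(key=lambda t: (t[1], t[0]))
    return CoreProteinSet(proteins=tuple(scored[:K]), K=K)


def write_core_proteins_tsv(
    docs: Sequence[Document], core: CoreProteinSet, disease_id: str,
    path: str | Path,
) -> None:
    """TSV report: rank, protein_id, a, b, c, d, p_value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tprotein_id\ta\tb\tc\td\tp_value\n")
        for rank, (pid, p) in enumerate(core, 1):
            t = comention_table(docs, pid, disease_id)
            fh.write(f"{rank}\t{pid}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{p:.6g}\n")
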