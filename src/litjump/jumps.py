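"""Empirical rank-jump p-values and weekly high-jumper detection.

A protein's weekly rank change (jump = initial rank − new rank; positive
means improvement toward rank 1) is judged against the historical
distribution of jumps that started from similar ranks: a 3-place gain near
the top is remarkable, the same gain at rank 15,000 is routine.  Because
not every (rank, jump) combination has been observed, jumps are pooled over
a rank window around the initial rank before the empirical tail probability
is computed.  Only upward jumps are tested; the typical background move is
a 1-place loss caused by someone else's gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


def rank_jump(initial_rank: int, new_rank: int) -> int:
    """Signed weekly rank change; positive = upward (improvement)."""
    if initial_rank < 1 or new_rank < 1:
        raise ValueError("ranks must be >= 1")
    return initial_rank - new_rank


def default_rank_window(rank: int) -> int:
    """Pooling half-width around an initial rank: max(5, round(0.1 * r)).

    Tight near the top of the list, where small jumps are already rare, and
    wide far down, where jumps of thousands of places occur.
    """
    return max(5, round(0.1 * rank))


@dataclass(frozen=True)
class JumpObservation:
    protein_id: str
    week: int
    initial_rank: int
    new_rank: int

    @property
    def jump(self) -> int:
        return self.initial_rank - self.new_rank


class JumpDistribution:
    """Smoothed empirical distribution of weekly jumps by initial rank.

    Holds every historical (initial rank, jump) observation; queries pool
    observations whose initial rank lies within the rank window of the
    queried rank.
    """

    def __init__(self, observations: Sequence[JumpObservation],
                 rank_window=default_rank_window) -> None:
        self.observations = tuple(observations)
        self.rank_window = rank_window
        self._ranks = np.array([o.initial_rank for o in observations], dtype=int)
        self._jumps = np.array([o.jump for o in observations], dtype=int)

    def __len__(self) -> int:
        return len(self.observations)

    def pooled_jumps(self, initial_rank: int) -> np.ndarray:
        """All historical jumps that started within the rank window."""
        h = self.rank_window(initial_rank)
        mask = np.abs(self._ranks - initial_rank) <= h
        return self._jumps[mask]

    def pooled_distribution(self, initial_rank: int) -> dict[int, float]:
        """Empirical probability of each pooled jump value (sums to 1)."""
        pooled = self.pooled_jumps(initial_rank)
        if pooled.size == 0:
            return {}
        vals, counts = np.unique(pooled, return_counts=True)
        return {int(v): float(c) / pooled.size for v, c in zip(vals, counts)}


def build_jump_distribution(
    rank_history: Mapping[int, Mapping[str, int]],
    upto_week: int | None = None,
    rank_window=default_rank_window,
) -> JumpDistribution:
    """Collect one jump observation per protein per consecutive week pair.

    ``rank_history`` maps week -> protein -> rank.  Only transitions whose
    arrival week is strictly before ``upto_week`` enter the distribution, so
    an evaluation week never contributes to its own null.
    """
    weeks = sorted(rank_history)
    if upto_week is not None:
        weeks = [w for w in weeks if w < upto_week]
    if len(weeks) < 2:
        raise ValueError(
            "need at least 2 weeks of rank history before jumps can be "
            "assessed; extend the burn-in period")
    obs: list[JumpObservation] = []
    for prev_w, new_w in zip(weeks[:-1], weeks[1:]):
        prev, new = rank_history[prev_w], rank_history[new_w]
        for pid, r0 in prev.items():
            r1 = new.get(pid)
            if r1 is not None:
                obs.append(JumpObservation(pid, new_w, r0, r1))
    return JumpDistribution(obs, rank_window=rank_window)


def jump_pvalue(dist: JumpDistribution, initial_rank: int, jump: int) -> float:
    """One-sided empirical p-value for an upward jump.

    ``p = (1 + #{pooled historical jumps >= jump}) / (1 + N_pooled)``;
    the add-one keeps every p-value strictly positive and the estimate
    valid.  Monotone non-increasing in the jump size.
    """
    pooled = dist.pooled_jumps(initial_rank)
    if pooled.size == 0:
        logger.warning("no pooled history at initial rank %d; p=1", initial_rank)
        return 1.0
    return float(1 + int((pooled >= jump).sum())) / (1 + pooled.size)


@dataclass(frozen=True)
class HighJumper:
    protein_id: str
    initial_rank: int
    new_rank: int
    jump: int
    p_value: float
    trigger_doc_id: str | None = None


def weekly_high_jumpers(
    prev_ranks: Mapping[str, int],
    new_ranks: Mapping[str, int],
    dist: JumpDistribution,
    alpha: float = 0.05,
    trigger_docs: Mapping[str, str] | None = None,
) -> list[HighJumper]:
    """Proteins whose upward jump this week is significant at ``alpha``.

    Both rank maps must cover the same protein universe.  Results are
    sorted by ascending p-value (ties by protein id); each entry may carry
    the week's top-scoring article for the protein — the abstract causing
    the jump.
    """
    if set(prev_ranks) != set(new_ranks):
        raise ValueError("previous and new rank maps cover different proteins")
    out: list[HighJumper] = []
    for pid in sorted(prev_ranks):
        j = rank_jump(prev_ranks[pid], new_ranks[pid])
        if j <= 0:
            continue
        p = jump_pvalue(dist, prev_ranks[pid], j)
        if p <= alpha:
            out.append(HighJumper(
                protein_id=pid, initial_rank=prev_ranks[pid],
                new_rank=new_ranks[pid], jump=j, p_value=p,
                trigger_doc_id=(trigger_docs or {}).get(pid)))
    out.sort(key=lambda h: (h.p_value, h.protein_id))
    return out
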