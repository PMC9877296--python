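"""Robust rank aggregation of per-iteration ranked lists.

Each entity's normalized ranks across L lists are scored by order-statistic
binomial tails: for the k-th smallest normalized rank r(k),

    beta_k = P(X >= k),  X ~ Binomial(L, r(k)),

rho is the minimum beta_k, and the p-value is the Bonferroni correction
min(1, rho * L) over the L order statistics.  Entities missing from a list
take the worst normalized rank 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RankedList:
    """One iteration's ordered entity list, best first."""

    iteration: int
    entities: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.entities)) != len(self.entities):
            raise ValueError("entities must be unique within a ranked list")


@dataclass(frozen=True)
class AggregationResult:
    entity: str
    rho: float
    p_value: float
    aggregate_rank: int


def _check_ranks(normalized_ranks: Sequence[float], n_lists: int) -> np.ndarray:
    r = np.asarray(normalized_ranks, dtype=float)
    if r.ndim != 1 or r.size != n_lists:
        raise ValueError("expected one normalized rank per list")
    if np.any(r <= 0.0) or np.any(r > 1.0):
        raise ValueError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise ValueError("normalized ranks must be sorted ascending")
    return r


def beta_scores(normalized_ranks: Sequence[float], n_lists: int) -> np.ndarray:
    """Binomial-tail score for each order statistic of the sorted ranks.

    Element k-1 is P(Binomial(n_lists, r(k)) >= k); ``scipy.stats.binom.sf``
    keeps this stable for hundreds of lists.
    """
    r = _check_ranks(normalized_ranks, n_lists)
    k = np.arange(1, n_lists + 1)
    return stats.binom.sf(k - 1, n_lists, r)


def rra_pvalue(normalized_ranks: Sequence[float], n_lists: int) -> tuple[float, float]:
    """(rho, p): minimum beta score and its Bonferroni-corrected p-value."""
    beta = beta_scores(normalized_ranks, n_lists)
    rho = float(beta.min())
    return rho, float(min(1.0, rho * n_lists))


def aggregate_rankings(
    lists: Sequence[RankedList],
    universe: Iterable[str],
) -> list[AggregationResult]:
    """Aggregate ranked lists over a fixed entity universe.

    The normalized rank of an entity in a list is its 1-based position
    divided by the universe size, or 1.0 when absent.  Results are sorted
    by p-value ascending (ties by name) and carry dense aggregate ranks.
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("universe is empty")
    if not lists:
        raise ValueError("need at least one ranked list")
    n_univ = len(universe)
    known = set(universe)
    for rl in lists:
        stray = set(rl.entities) - known
        if stray:
            raise ValueError(f"entities outside universe: {sorted(stray)[:5]}")

    n_lists = len(lists)
    positions = [{e: i + 1 for i, e in enumerate(rl.entities)} for rl in lists]
    scored: list[tuple[float, float, str]] = []
    for entity in universe:
        ranks = np.sort(
            [pos.get(entity, n_univ) / n_univ for pos in positions]
        )
        rho, p = rra_pvalue(ranks, n_lists)
        scored.append((p, rho, entity))
    scored.sort(key=lambda t: (t[0], t[2]))

    # dense rank over p-values: tied p shares a rank
    out: list[AggregationResult] = []
    rank = 0
    prev_p: float | None = None
    for p, rho, entity in scored:
        if prev_p is None or p != prev_p:
            rank += 1
            prev_p = p
        out.append(AggregationResult(entity=entity, rho=rho, p_value=p, aggregate_rank=rank))
    return out
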