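"""End-to-end orchestration: outer MCCV over filter/balance/split, grouping,
scoring, cumulative modeling, then robust rank aggregation of the
per-iteration disease and miRNA orderings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import grouping, modeling, preprocess, scoring
from .aggregate import AggregationResult, RankedList, aggregate_rankings
from .io_formats import ExpressionDataset, GroupTable
from .modeling import CumulativeResult
from .preprocess import DegenerateSplitError
from .scoring import ClassifierConfig, GroupScore

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass
class PipelineConfig:
    """All tunable knobs of one run; defaults follow the reference protocol."""

    inner_reps: int = 5
    inner_train_frac: float = 0.7
    top_n_filter: int = 1000
    max_k: int = 10
    trees: int = 100
    threshold: float = 0.5
    min_group_size: int = 1
    group_cap: int | None = None

    @property
    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(trees=self.trees)


@dataclass
class IterationResult:
    index: int
    seed: int
    scores: list[GroupScore]
    cumulative: list[CumulativeResult]
    disease_order: list[str]
    mirna_order: list[str]


@dataclass
class ResultBundle:
    iterations: list[IterationResult]
    cumulative_mean: list[CumulativeResult]
    disease_results: list[AggregationResult]
    mirna_results: list[AggregationResult]
    log_lines: list[str] = field(default_factory=list)


def derive_seed(master_seed: int, counter: int) -> int:
    """Counter-based, platform-stable seed derivation."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0])


def _mirna_order(
    train: ExpressionDataset,
    ranked: Sequence[GroupScore],
    groups: GroupTable,
    max_k: int,
) -> list[str]:
    """Rank miRNAs of the top-k groups: each inherits its best group score."""
    top = ranked[: min(max_k, len(ranked))]
    available = set(train.feature_ids)
    best: dict[str, float] = {}
    for gs in top:
        for mirna in groups[gs.group] & available:
            if mirna not in best or gs.score > best[mirna]:
                best[mirna] = gs.score
    return sorted(best, key=lambda m: (-best[m], m))


def run_iteration(
    ds: ExpressionDataset,
    groups: GroupTable,
    outer_train_frac: float,
    cfg: PipelineConfig,
    seed: int,
    index: int,
) -> IterationResult:
    """One outer MCCV iteration: split, balance, filter, group, score, model.

    The held-out test partition is touched only by the cumulative model
    evaluation.
    """
    states = np.random.SeedSequence(seed).generate_state(4)
    split = preprocess.stratified_split(ds, outer_train_frac, int(states[0]))
    train, test = split.apply(ds)
    train = preprocess.undersample(train, int(states[1]))
    train = preprocess.ttest_rank_filter(train, cfg.top_n_filter)
    test = test.subset_features(train.feature_ids)

    ranked = scoring.score_all_groups(
        train,
        groups,
        cfg=cfg.classifier,
        seed=int(states[2]),
        inner_reps=cfg.inner_reps,
        inner_train_frac=cfg.inner_train_frac,
        min_size=cfg.min_group_size,
        cap=cfg.group_cap,
    )
    cumulative = modeling.evaluate_cumulative(
        train,
        test,
        ranked,
        groups,
        max_k=cfg.max_k,
        classifier_cfg=cfg.classifier,
        seed=int(states[3]),
        threshold=cfg.threshold,
    )
    return IterationResult(
        index=index,
        seed=seed,
        scores=ranked,
        cumulative=cumulative,
        disease_order=[gs.group for gs in ranked],
        mirna_order=_mirna_order(train, ranked, groups, cfg.max_k),
    )


def _mean_cumulative(iterations: Sequence[IterationResult]) -> list[CumulativeResult]:
    by_k: dict[int, list[CumulativeResult]] = {}
    for it in iterations:
        for c in it.cumulative:
            by_k.setdefault(c.k, []).append(c)
    out = []
    for k in sorted(by_k):
        rows = by_k[k]
        out.append(
            CumulativeResult(
                k=k,
                n_mirnas=float(np.mean([c.n_mirnas for c in rows])),
                accuracy=float(np.mean([c.accuracy for c in rows])),
                sensitivity=float(np.mean([c.sensitivity for c in rows])),
                specificity=float(np.mean([c.specificity for c in rows])),
                auc=float(np.mean([c.auc for c in rows])),
            )
        )
    return out


def run_mirdisnet(
    ds: ExpressionDataset,
    groups: GroupTable,
    outer_iters: int = 100,
    outer_train_frac: float = 0.9,
    cfg: PipelineConfig | None = None,
    master_seed: int = 0,
) -> ResultBundle:
    """Run the full pipeline and aggregate per-iteration rankings.

    Exactly ``outer_iters`` successful iterations contribute; an iteration
    whose split or balance leaves a single-class partition is re-drawn with
    the next derived seed and logged.
    """
    if outer_iters < 1:
        raise ValueError("outer_iters must be >=1")
    ds.require_two_classes()
    cfg = cfg or PipelineConfig()

    iterations: list[IterationResult] = []
    log_lines: list[str] = []
    counter = 0
    while len(iterations) < outer_iters:
        if counter >= outer_iters + _MAX_REDRAWS:
            raise RuntimeError("too many degenerate iterations; check class sizes")
        seed = derive_seed(master_seed, counter)
        counter += 1
        try:
            it = run_iteration(ds, groups, outer_train_frac, cfg, seed, len(iterations) + 1)
        except DegenerateSplitError as exc:
            line = f"iter=redraw seed={seed} reason={exc}"
            logger.warning(line)
            log_lines.append(line)
            continue
        k_last = it.cumulative[-1]
        line = (
            f"iter={it.index} seed={seed} groups={len(it.scores)} "
            f"top={it.scores[0].group} k{k_last.k}_auc={k_last.auc:.4f}"
        )
        logger.info(line)
        log_lines.append(line)
        iterations.append(it)

    disease_universe = set(groups.groups)
    covered = set().union(*(set(groups[g]) for g in groups)) & set(ds.feature_ids)
    disease_lists = [
        RankedList(iteration=it.index, entities=tuple(it.disease_order)) for it in iterations
    ]
    mirna_lists = [
        RankedList(iteration=it.index, entities=tuple(it.mirna_order)) for it in iterations
    ]
    return ResultBundle(
        iterations=iterations,
        cumulative_mean=_mean_cumulative(iterations),
        disease_results=aggregate_rankings(disease_lists, disease_universe),
        mirna_results=aggregate_rankings(mirna_lists, covered),
        log_lines=log_lines,
    )
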