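"""Scoring component: mean MCCV accuracy per disease group, with dense ranks.

Each group's two-class sub-dataset is scored by repeated stratified
train/test splitting (default 70/30, five repetitions) of a random-forest
classifier; the score is the arithmetic mean test accuracy.  Scores are
dense-ranked after rounding to four decimals, so reported ties share a rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .io_formats import POS, ExpressionDataset, GroupTable
from . import grouping, preprocess

SCORE_DECIMALS = 4


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest settings shared by the scoring and modeling stages."""

    trees: int = 100


def make_classifier(cfg: ClassifierConfig, random_state: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=cfg.trees, random_state=random_state)


@dataclass(frozen=True)
class GroupScore:
    group: str
    score: float
    rank: int


def _derived_states(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)


def score_group(
    subds: ExpressionDataset,
    inner_reps: int = 5,
    inner_train_frac: float = 0.7,
    classifier_cfg: ClassifierConfig | None = None,
    seed: int = 0,
) -> float:
    """Mean test accuracy of ``inner_reps`` stratified MCCV repetitions."""
    if inner_reps < 1:
        raise ValueError("inner_reps must be >=1")
    subds.require_two_classes()
    cfg = classifier_cfg or ClassifierConfig()
    states = _derived_states(seed, 2 * inner_reps)
    accs = []
    for i in range(inner_reps):
        split = preprocess.stratified_split(subds, inner_train_frac, int(states[2 * i]))
        train, test = split.apply(subds)
        clf = make_classifier(cfg, int(states[2 * i + 1]))
        clf.fit(train.values, train.labels.astype(str))
        accs.append(float(np.mean(clf.predict(test.values) == test.labels.astype(str))))
    return float(np.mean(accs))


def dense_rank(scores: Sequence[float], decimals: int = SCORE_DECIMALS) -> list[int]:
    """Dense ranks (1 = best) for scores, higher score = better.

    Scores are rounded to ``decimals`` before comparison so that values that
    print equal share a rank; rank values over the list are 1..#distinct
    with no gaps.
    """
    rounded = [round(float(s), decimals) for s in scores]
    distinct = sorted(set(rounded), reverse=True)
    pos = {s: i + 1 for i, s in enumerate(distinct)}
    return [pos[s] for s in rounded]


def score_all_groups(
    train: ExpressionDataset,
    groups: GroupTable,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    inner_reps: int = 5,
    inner_train_frac: float = 0.7,
    min_size: int = 1,
    cap: int | None = None,
) -> list[GroupScore]:
    """Score every group surviving intersection with ``train`` features.

    Returns one :class:`GroupScore` per group, ordered by score descending
    then group name ascending, with dense ranks.  Per-group seeds are
    derived from ``seed`` and the group's position in name-sorted order, so
    the result is invariant to group insertion order.
    """
    subdatasets = grouping.build_group_subdatasets(train, groups, min_size=min_size, cap=cap)
    names = sorted(subdatasets)
    states = _derived_states(seed, len(names))
    raw: dict[str, float] = {}
    for i, name in enumerate(names):
        raw[name] = score_group(
            subdatasets[name],
            inner_reps=inner_reps,
            inner_train_frac=inner_train_frac,
            classifier_cfg=cfg,
            seed=int(states[i]),
        )
    if not raw:
        raise ValueError("no scorable groups")
    ordered = sorted(raw, key=lambda g: (-round(raw[g], SCORE_DECIMALS), g))
    ranks = dense_rank([raw[g] for g in ordered])
    return [GroupScore(group=g, score=raw[g], rank=r) for g, r in zip(ordered, ranks)]
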