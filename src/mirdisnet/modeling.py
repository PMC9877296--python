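"""Modeling component: cumulative top-k training/evaluation and binary metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import NEG, POS, ExpressionDataset, GroupTable
from .scoring import ClassifierConfig, GroupScore, make_classifier


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


@dataclass(frozen=True)
class CumulativeResult:
    """Performance of the model built from the union of the top-k groups."""

    k: int
    n_mirnas: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


def binary_metrics(labels: Sequence[str], scores: Sequence[float], threshold: float = 0.5) -> Metrics:
    """Confusion-matrix metrics at ``threshold`` plus rank-statistic AUC.

    Predictions are pos where score >= threshold, with pos as the positive
    class.  AUC is the Mann-Whitney concordance of pos over neg scores
    (ties count one half), computed from the scores without thresholding.
    """
    labels = np.asarray(labels, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    is_pos = labels == POS
    is_neg = labels == NEG
    n_pos, n_neg = int(is_pos.sum()), int(is_neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    pred_pos = scores >= threshold
    tp = int(np.sum(pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & is_neg))
    fp = int(np.sum(pred_pos & is_neg))
    fn = int(np.sum(~pred_pos & is_pos))

    ranks = stats.rankdata(scores)  # average ranks: ties contribute 1/2
    auc = (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    return Metrics(
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=float(auc),
    )


def cumulative_feature_union(
    train: ExpressionDataset,
    ranked_groups: Sequence[GroupScore],
    groups: GroupTable,
    k: int,
) -> list[str]:
    """Union of the top-k groups' members intersected with ``train`` features.

    Features come out in ``train`` feature order (deduplicated), so the
    union is deterministic and nested across k.
    """
    members: set[str] = set()
    for gs in ranked_groups[:k]:
        members |= groups[gs.group]
    return [f for f in train.feature_ids if f in members]


def evaluate_cumulative(
    train: ExpressionDataset,
    test: ExpressionDataset,
    ranked_groups: Sequence[GroupScore],
    groups: GroupTable,
    max_k: int = 10,
    classifier_cfg: ClassifierConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[CumulativeResult]:
    """Fit and evaluate one fresh classifier per cumulative top-k feature set.

    For k = 1..min(max_k, #groups): restrict ``train`` to the union of the
    top-k groups' features, fit a random forest, and score the held-out
    ``test`` partition with probability scores for the pos class.
    """
    if not ranked_groups:
        raise ValueError("ranked_groups is empty")
    if max_k < 1:
        raise ValueError("max_k must be >=1")
    cfg = classifier_cfg or ClassifierConfig()
    n_k = min(max_k, len(ranked_groups))
    states = np.random.SeedSequence(seed).generate_state(n_k) % np.uint32(2**31)
    results: list[CumulativeResult] = []
    for k in range(1, n_k + 1):
        union = cumulative_feature_union(train, ranked_groups, groups, k)
        if not union:
            if k == 1:
                raise ValueError("empty feature union at k=1")
            continue
        sub_train = train.subset_features(union)
        sub_test = test.subset_features(union)
        clf = make_classifier(cfg, int(states[k - 1]))
        clf.fit(sub_train.values, sub_train.labels.astype(str))
        pos_col = list(clf.classes_).index(POS)
        probs = clf.predict_proba(sub_test.values)[:, pos_col]
        m = binary_metrics(sub_test.labels, probs, threshold=threshold)
        results.append(
            CumulativeResult(
                k=k,
                n_mirnas=float(len(union)),
                accuracy=m.accuracy,
                sensitivity=m.sensitivity,
                specificity=m.specificity,
                auc=m.auc,
            )
        )
    return results
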