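"""Noise filtering, class balancing and stratified Monte-Carlo splitting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import NEG, POS, ExpressionDataset


class DegenerateSplitError(ValueError):
    """A split or balance operation would leave a partition without both classes."""


@dataclass
class SplitSpec:
    """One train/test partition of a dataset's sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")

    def apply(self, ds: ExpressionDataset) -> tuple[ExpressionDataset, ExpressionDataset]:
        return ds.subset_samples(self.train_indices), ds.subset_samples(self.test_indices)


def welch_t(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided Welch t statistics (pos minus neg) and p-values.

    Features constant in both classes with equal means get t = 0, p = 1;
    zero-variance features with differing means get +/-inf t and p = 0.
    """
    pos = ds.values[ds.labels == POS, :]
    neg = ds.values[ds.labels == NEG, :]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs >=2 samples for the t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(pos, neg, equal_var=False, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mean_diff = pos.mean(axis=0) - neg.mean(axis=0)
    zero_se = ~np.isfinite(t)
    # zero pooled standard error: separate equal-mean (null) from separating features
    equal = zero_se & np.isclose(mean_diff, 0.0)
    sep = zero_se & ~np.isclose(mean_diff, 0.0)
    t[equal], p[equal] = 0.0, 1.0
    t[sep] = np.sign(mean_diff[sep]) * np.inf
    p[sep] = 0.0
    p[~np.isfinite(p)] = 1.0
    return t, p


def ttest_rank_filter(ds: ExpressionDataset, n_keep: int) -> ExpressionDataset:
    """Keep the ``n_keep`` most differentially expressed features.

    Features are ranked by two-sided Welch t-test p-value ascending, ties
    broken by |t| descending, then by name; samples and labels are
    unchanged.  The returned dataset's feature order is the rank order.
    """
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    t, p = welch_t(ds)
    abs_t = np.abs(t)
    order = sorted(
        range(ds.n_features),
        key=lambda j: (p[j], -abs_t[j], ds.feature_ids[j]),
    )
    keep = order[: min(n_keep, ds.n_features)]
    return ds.subset_features([ds.feature_ids[j] for j in keep])


def undersample(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Balance classes by uniform down-sampling of the majority class.

    All minority-class samples are kept; majority-class samples are drawn
    without replacement down to the minority size.  Input sample order is
    preserved.  Deterministic given ``seed``.
    """
    counts = ds.class_counts()
    if counts[POS] == 0 or counts[NEG] == 0:
        raise DegenerateSplitError("undersample requires both classes present")
    if counts[POS] == counts[NEG]:
        return ds.subset_samples(np.arange(ds.n_samples))
    minority = POS if counts[POS] < counts[NEG] else NEG
    majority = NEG if minority == POS else POS
    maj_idx = np.flatnonzero(ds.labels == majority)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(maj_idx, size=counts[minority], replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(ds.labels == minority), chosen]))
    return ds.subset_samples(keep)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(ds: ExpressionDataset, train_frac: float, seed: int) -> SplitSpec:
    """Stratified random train/test split.

    Per class, round(train_frac x class size) samples (round half up) go to
    train and the remainder to test, chosen uniformly at random within the
    class.  Raises :class:`DegenerateSplitError` if either partition would
    miss a class.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (POS, NEG):
        cls_idx = np.flatnonzero(ds.labels == cls)
        n = cls_idx.size
        if n < 2:
            raise DegenerateSplitError(f"class {cls!r} has {n} samples; need >=2 to split")
        n_train = _round_half_up(train_frac * n)
        if n_train == 0 or n_train == n:
            raise DegenerateSplitError(
                f"split leaves class {cls!r} empty in one partition (n={n}, frac={train_frac})"
            )
        perm = rng.permutation(cls_idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return SplitSpec(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        seed=seed,
    )
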