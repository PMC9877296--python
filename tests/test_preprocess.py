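import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdisnet import stratified_split, ttest_rank_filter, undersample
from mirdisnet.preprocess import DegenerateSplitError, welch_t

from .conftest import build_ds


def welch_oracle(a, b):
    """Hand-written Welch t for one feature (independent of the scipy route)."""
    m1, m2 = np.mean(a), np.mean(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = v1 / len(a) + v2 / len(b)
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / len(a)) ** 2 / (len(a) - 1) + (v2 / len(b)) ** 2 / (len(b) - 1))
    return t, df


def random_two_class(rng, n_pos, n_neg, m):
    values = rng.lognormal(3, 1, (n_pos + n_neg, m))
    return build_ds(values, ["pos"] * n_pos + ["neg"] * n_neg)


class TestWelchT:
    def test_matches_manual_formula(self):
        rng = np.random.default_rng(11)
        ds = random_two_class(rng, 8, 6, 5)
        t, p = welch_t(ds)
        for j in range(5):
            t_ref, _ = welch_oracle(ds.values[:8, j], ds.values[8:, j])
            assert t[j] == pytest.approx(t_ref, rel=1e-12)

    def test_constant_feature_t0_p1_ranked_last(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(3, 1, (10, 3))
        values[:, 1] = 4.2  # identical in both classes
        ds = build_ds(values, ["pos"] * 5 + ["neg"] * 5)
        t, p = welch_t(ds)
        assert t[1] == 0.0 and p[1] == 1.0
        kept = ttest_rank_filter(ds, 3)
        assert kept.feature_ids[-1] == ds.feature_ids[1]

    def test_separating_zero_variance_feature_ranked_first(self):
        values = np.ones((8, 2))
        values[:, 0] = [9, 9, 9, 9, 1, 1, 1, 1]
        values[:, 1] = np.arange(8) * 1.0 + 1
        ds = build_ds(values, ["pos"] * 4 + ["neg"] * 4)
        kept = ttest_rank_filter(ds, 2)
        assert kept.feature_ids[0] == ds.feature_ids[0]

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        ds = random_two_class(rng, 7, 9, 12)
        swapped = build_ds(
            ds.values,
            ["neg" if l == "pos" else "pos" for l in ds.labels],
            features=list(ds.feature_ids),
        )
        t1, p1 = welch_t(ds)
        t2, p2 = welch_t(swapped)
        np.testing.assert_allclose(t1, -t2, rtol=1e-12)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)
        assert set(ttest_rank_filter(ds, 4).feature_ids) == set(
            ttest_rank_filter(swapped, 4).feature_ids
        )


class TestTtestRankFilter:
    def test_n_keep_at_least_n_features_is_identity_set(self):
        rng = np.random.default_rng(5)
        ds = random_two_class(rng, 5, 5, 8)
        kept = ttest_rank_filter(ds, 100)
        assert set(kept.feature_ids) == set(ds.feature_ids)
        assert kept.sample_ids == ds.sample_ids
        assert list(kept.labels) == list(ds.labels)

    def test_invalid_args(self):
        rng = np.random.default_rng(5)
        ds = random_two_class(rng, 5, 5, 4)
        with pytest.raises(ValueError):
            ttest_rank_filter(ds, 0)
        tiny = build_ds([[1.0], [2.0], [3.0]], ["pos", "neg", "neg"])
        with pytest.raises(ValueError, match=">=2 samples"):
            ttest_rank_filter(tiny, 1)

    def test_planted_feature_recovered(self):
        # one feature shifted by 2 pooled SDs among 99 nulls; n=50/50
        hits = 0
        for sim in range(100):
            rng = np.random.default_rng(1000 + sim)
            values = rng.normal(0, 1, (100, 100))
            values[:50, 0] += 2.0
            ds = build_ds(values - values.min() + 0.01, ["pos"] * 50 + ["neg"] * 50)
            kept = ttest_rank_filter(ds, 10)
            hits += ds.feature_ids[0] in kept.feature_ids
        assert hits >= 95


class TestUndersample:
    def test_majority_reduced(self, make_ds):
        rng = np.random.default_rng(0)
        ds = make_ds(rng.lognormal(3, 1, (30, 3)), ["pos"] * 20 + ["neg"] * 10)
        out = undersample(ds, seed=1)
        counts = out.class_counts()
        assert counts == {"pos": 10, "neg": 10}
        # all minority samples retained
        assert set(np.asarray(ds.sample_ids)[20:]) <= set(out.sample_ids)

    def test_balanced_identity(self, make_ds):
        rng = np.random.default_rng(0)
        ds = make_ds(rng.lognormal(3, 1, (30, 2)), ["pos"] * 15 + ["neg"] * 15)
        out = undersample(ds, seed=5)
        assert out.sample_ids == ds.sample_ids

    def test_deterministic(self, make_ds):
        rng = np.random.default_rng(0)
        ds = make_ds(rng.lognormal(3, 1, (25, 2)), ["pos"] * 18 + ["neg"] * 7)
        assert undersample(ds, seed=9).sample_ids == undersample(ds, seed=9).sample_ids

    def test_single_class_errors(self, make_ds):
        ds = make_ds([[1.0], [2.0]], ["pos", "pos"])
        with pytest.raises(DegenerateSplitError):
            undersample(ds, seed=0)

    @given(n_pos=st.integers(1, 20), n_neg=st.integers(1, 20), seed=st.integers(0, 99))
    @settings(max_examples=30, deadline=None)
    def test_output_subset_and_balanced(self, n_pos, n_neg, seed):
        rng = np.random.default_rng(42)
        ds = build_ds(
            rng.lognormal(3, 1, (n_pos + n_neg, 2)), ["pos"] * n_pos + ["neg"] * n_neg
        )
        out = undersample(ds, seed=seed)
        counts = out.class_counts()
        assert counts["pos"] == counts["neg"] == min(n_pos, n_neg)
        assert set(out.sample_ids) <= set(ds.sample_ids)


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n_pos,n_neg,frac,want_train",
        [(10, 10, 0.7, (7, 7)), (50, 50, 0.9, (45, 45)), (10, 20, 0.7, (7, 14))],
    )
    def test_exact_proportions(self, n_pos, n_neg, frac, want_train):
        rng = np.random.default_rng(1)
        ds = build_ds(
            rng.lognormal(3, 1, (n_pos + n_neg, 2)), ["pos"] * n_pos + ["neg"] * n_neg
        )
        split = stratified_split(ds, frac, seed=3)
        train, test = split.apply(ds)
        assert (train.class_counts()["pos"], train.class_counts()["neg"]) == want_train
        assert train.n_samples + test.n_samples == ds.n_samples

    @given(
        n_pos=st.integers(4, 30),
        n_neg=st.integers(4, 30),
        frac=st.floats(0.2, 0.8),
        seed=st.integers(0, 999),
    )
    @settings(max_examples=40, deadline=None)
    def test_partition_property(self, n_pos, n_neg, frac, seed):
        rng = np.random.default_rng(7)
        ds = build_ds(
            rng.lognormal(3, 1, (n_pos + n_neg, 2)), ["pos"] * n_pos + ["neg"] * n_neg
        )
        try:
            split = stratified_split(ds, frac, seed=seed)
        except DegenerateSplitError:
            return
        joined = np.sort(np.concatenate([split.train_indices, split.test_indices]))
        np.testing.assert_array_equal(joined, np.arange(ds.n_samples))
        # per-class train count equals round-half-up of frac * class size
        train, _ = split.apply(ds)
        for cls, n_cls in (("pos", n_pos), ("neg", n_neg)):
            assert train.class_counts()[cls] == int(math.floor(frac * n_cls + 0.5))

    def test_degenerate_errors(self, make_ds):
        ds = make_ds([[1.0], [2.0], [3.0], [4.0]], ["pos", "pos", "neg", "neg"])
        with pytest.raises(DegenerateSplitError):
            stratified_split(ds, 0.95, seed=0)  # train would take the full class
        tiny = make_ds([[1.0], [2.0], [3.0]], ["pos", "neg", "neg"])
        with pytest.raises(DegenerateSplitError):
            stratified_split(tiny, 0.5, seed=0)

    def test_deterministic(self, make_ds):
        rng = np.random.default_rng(1)
        ds = build_ds(rng.lognormal(3, 1, (20, 2)), ["pos"] * 10 + ["neg"] * 10)
        s1 = stratified_split(ds, 0.7, seed=4)
        s2 = stratified_split(ds, 0.7, seed=4)
        np.testing.assert_array_equal(s1.train_indices, s2.train_indices)
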