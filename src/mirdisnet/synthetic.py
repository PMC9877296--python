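"""Synthetic two-class expression data with planted group structure.

Expression values are exp of a Gaussian log-signal (meanlog 3, sdlog 1), an
RPM-like non-negative proxy.  A chosen subset of features is differentially
expressed: the pos class's log-signal mean is shifted by ``effect_size``
pooled standard deviations.  Enriched groups draw most members from the DE
features; background groups draw only from nulls.  Group sizes follow a
right-skewed (truncated exponential) distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import NEG, POS, ExpressionDataset, GroupTable

MEANLOG = 3.0
SDLOG = 1.0


@dataclass
class SyntheticConfig:
    n_pos: int = 30
    n_neg: int = 30
    n_features: int = 200
    n_de: int = 20
    effect_size: float = 1.0
    n_groups: int = 20
    n_enriched: int = 3
    group_size_range: tuple[int, int] = (5, 15)
    enrichment_purity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if not 0 <= self.n_de <= self.n_features:
            raise ValueError("n_de must lie in [0, n_features]")
        if not 0 <= self.n_enriched <= self.n_groups:
            raise ValueError("n_enriched must lie in [0, n_groups]")
        if not 0.0 <= self.enrichment_purity <= 1.0:
            raise ValueError("enrichment_purity must lie in [0, 1]")
        lo, hi = self.group_size_range
        if lo < 1 or hi < lo:
            raise ValueError("group_size_range must satisfy 1 <= min <= max")
        n_null = self.n_features - self.n_de
        if hi > n_null and self.n_groups > self.n_enriched:
            raise ValueError("background group size may exceed the null feature pool")
        if self.n_enriched:
            need_de = math.ceil(self.enrichment_purity * hi)
            if need_de > self.n_de and self.enrichment_purity > 0:
                raise ValueError("enriched group size may exceed the DE feature pool")
            if hi - math.ceil(self.enrichment_purity * lo) > n_null:
                raise ValueError("enriched group filler may exceed the null feature pool")


def _skewed_sizes(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    if lo == hi:
        return np.full(n, lo)
    draw = lo + np.floor(rng.exponential(scale=(hi - lo) / 3.0, size=n))
    return np.clip(draw, lo, hi).astype(int)


def generate(cfg: SyntheticConfig) -> tuple[ExpressionDataset, GroupTable, dict[str, set[str]]]:
    """Generate (dataset, groups, truth) with planted differential structure.

    ``truth`` has keys ``"groups"`` (enriched group names) and ``"features"``
    (DE miRNA names).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pos + cfg.n_neg
    width = max(4, len(str(cfg.n_features)))
    feature_ids = [f"mir-{i:0{width}d}" for i in range(1, cfg.n_features + 1)]
    de_idx = rng.choice(cfg.n_features, size=cfg.n_de, replace=False)
    de_mask = np.zeros(cfg.n_features, dtype=bool)
    de_mask[de_idx] = True

    log_signal = rng.normal(MEANLOG, SDLOG, size=(n, cfg.n_features))
    log_signal[: cfg.n_pos, de_mask] += cfg.effect_size * SDLOG
    values = np.exp(log_signal)
    labels = np.array([POS] * cfg.n_pos + [NEG] * cfg.n_neg, dtype=object)
    ds = ExpressionDataset(
        sample_ids=[f"sample-{i:04d}" for i in range(1, n + 1)],
        feature_ids=feature_ids,
        values=values,
        labels=labels,
    )

    de_pool = [feature_ids[i] for i in np.flatnonzero(de_mask)]
    null_pool = [feature_ids[i] for i in np.flatnonzero(~de_mask)]
    sizes = _skewed_sizes(rng, cfg.n_groups, *cfg.group_size_range)
    gwidth = max(3, len(str(cfg.n_groups)))
    groups: dict[str, frozenset[str]] = {}
    enriched_names: set[str] = set()
    for g in range(cfg.n_groups):
        name = f"disease-{g + 1:0{gwidth}d}"
        size = int(sizes[g])
        if g < cfg.n_enriched:
            n_from_de = min(math.ceil(cfg.enrichment_purity * size), len(de_pool))
            n_fill = size - n_from_de
            if n_fill > len(null_pool):
                raise ValueError("group size exceeds the available feature pools")
            members = list(rng.choice(de_pool, size=n_from_de, replace=False))
            members += list(rng.choice(null_pool, size=n_fill, replace=False))
            enriched_names.add(name)
        else:
            if size > len(null_pool):
                raise ValueError("group size exceeds the null feature pool")
            members = list(rng.choice(null_pool, size=size, replace=False))
        groups[name] = frozenset(members)

    table = GroupTable(groups=groups)
    truth = {"groups": enriched_names, "features": set(de_pool)}
    return ds, table, truth
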