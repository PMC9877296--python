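"""Group component: per-disease two-class sub-datasets from prior knowledge."""

from __future__ import annotations

import logging

from .io_formats import ExpressionDataset, GroupTable

logger = logging.getLogger(__name__)


def group_size_distribution(groups: GroupTable, ds: ExpressionDataset) -> dict[str, int]:
    """Intersected member count per group (before any dropping)."""
    available = set(ds.feature_ids)
    return {name: len(groups[name] & available) for name in groups}


def build_group_subdatasets(
    ds: ExpressionDataset,
    groups: GroupTable,
    min_size: int = 1,
    cap: int | None = None,
) -> dict[str, ExpressionDataset]:
    """Extract one two-class sub-dataset per disease group.

    Each sub-dataset keeps ``ds``'s samples and labels and restricts the
    features to the intersection of the group's members with ``ds``'s
    features (in ``ds`` feature order, so a rank-ordered input preserves
    rank order).  Groups with fewer than ``max(min_size, 1)`` intersected
    members are dropped and logged.  ``cap`` truncates every group to its
    first ``cap`` intersected features in ``ds`` order — with a t-test
    rank-ordered ``ds`` this equalizes the number of miRNAs per group.
    """
    if len(groups) == 0:
        raise ValueError("group table is empty")
    threshold = max(min_size, 1)
    out: dict[str, ExpressionDataset] = {}
    for name in groups:
        members = groups[name]
        feats = [f for f in ds.feature_ids if f in members]
        if cap is not None:
            feats = feats[:cap]
        if len(feats) < threshold:
            logger.info("dropping group %r: %d members after intersection", name, len(feats))
            continue
        out[name] = ds.subset_features(feats)
    if not out:
        raise ValueError("every group is empty after intersection with the dataset")
    return out
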