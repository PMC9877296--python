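"""Tabular input/output: expression matrices, association tables, result tables.

Expression input is delimited text (tab or comma, auto-detected): first
column sample id, one column of class labels (``pos``/``neg``), remaining
columns numeric miRNA features.  Associations come as a two-column table
(disease, miRNA) or as GMT.  All miRNA identifiers are normalized by
lowercasing; paralogs (e.g. ``hsa-mir-125b-1``) stay distinct.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POS = "pos"
NEG = "neg"


class InputFormatError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_mirna(name: str) -> str:
    """Normalize a miRNA identifier: strip whitespace, lowercase the token."""
    return name.strip().lower()


@dataclass
class ExpressionDataset:
    """A two-class expression matrix: samples x miRNA features.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    feature_ids : list of str
        Unique normalized miRNA names, one per matrix column.
    values : ndarray of shape (n_samples, n_features)
        Non-negative, RPM-like expression values.
    labels : ndarray of str, shape (n_samples,)
        Per-sample class, each ``"pos"`` or ``"neg"``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise InputFormatError("sample ids, labels and matrix rows disagree")
        if len(self.feature_ids) != m:
            raise InputFormatError("feature ids and matrix columns disagree")
        if len(set(self.sample_ids)) != n:
            raise InputFormatError("duplicate sample ids")
        if len(set(self.feature_ids)) != m:
            raise InputFormatError("duplicate feature ids")
        if np.isnan(self.values).any():
            raise InputFormatError("matrix contains missing values")
        bad = set(self.labels) - {POS, NEG}
        if bad:
            raise InputFormatError(f"labels outside {{pos, neg}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {POS: int(np.sum(self.labels == POS)), NEG: int(np.sum(self.labels == NEG))}

    def require_two_classes(self) -> None:
        counts = self.class_counts()
        if counts[POS] == 0 or counts[NEG] == 0:
            raise InputFormatError("both classes must be present")

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx, :],
            labels=self.labels[idx],
        )

    def subset_features(self, features: Sequence[str]) -> "ExpressionDataset":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[f] for f in features]
        except KeyError as exc:
            raise KeyError(f"feature not in dataset: {exc.args[0]}") from exc
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            feature_ids=list(features),
            values=self.values[:, cols],
            labels=self.labels,
        )


@dataclass
class GroupTable:
    """Prior knowledge: disease name -> set of normalized miRNA names."""

    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for name, members in self.groups.items():
            members = frozenset(normalize_mirna(m) for m in members)
            if not members:
                raise InputFormatError(f"group {name!r} has no members")
            cleaned[name] = members
        self.groups = cleaned

    @property
    def t(self) -> int:
        """Number of groups."""
        return len(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.groups[name]

    def __iter__(self):
        return iter(self.groups)


def _sniff_delimiter(sample: str) -> str:
    # tab wins when present: disease names may legitimately contain commas
    if "\t" in sample:
        return "\t"
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return ","


def read_expression(
    path: str | Path,
    label_field: str = "class",
    label_map: Mapping[str, str] | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    The first column holds sample ids, ``label_field`` the class labels and
    every other column a numeric miRNA feature.  Rows containing any missing
    value are removed.  ``label_map`` maps nonstandard labels onto
    ``pos``/``neg``; without it, labels must be case-insensitive pos/neg.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"cannot read expression table {path}: {exc}") from exc
    if label_field not in df.columns:
        raise InputFormatError(f"label column {label_field!r} not found in {path}")

    df = df.dropna(axis=0, how="any")
    if df.shape[0] == 0:
        raise InputFormatError("no samples survive the missing-value filter")

    raw_labels = df[label_field].astype(str)
    if label_map is not None:
        mapping = {str(k).strip().lower(): v for k, v in label_map.items()}
    else:
        mapping = {POS: POS, NEG: NEG}
    labels = []
    for lab in raw_labels:
        key = lab.strip().lower()
        if key not in mapping or mapping[key] not in (POS, NEG):
            raise InputFormatError(f"unrecognized class label {lab!r}")
        labels.append(mapping[key])

    feat_df = df.drop(columns=[label_field])
    feature_ids = [normalize_mirna(str(c)) for c in feat_df.columns]
    dupes = {f for f in feature_ids if feature_ids.count(f) > 1}
    if dupes:
        raise InputFormatError(
            f"duplicate feature names after normalization: {sorted(dupes)}"
        )
    try:
        values = feat_df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"non-numeric feature values: {exc}") from exc

    return ExpressionDataset(
        sample_ids=[str(s) for s in df.index],
        feature_ids=feature_ids,
        values=values,
        labels=np.asarray(labels, dtype=object),
    )


def read_associations(path: str | Path, fmt: str | None = None) -> GroupTable:
    """Read a disease->miRNA association table.

    Two formats are accepted: a two-column delimited table (disease, miRNA),
    one association per row; or GMT (group, description, member...).  Format
    is taken from ``fmt`` (``"pairs"``/``"gmt"``) or inferred from the file
    suffix, defaulting to pairs.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputFormatError(f"cannot read associations {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputFormatError(f"empty association file: {path}")

    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "pairs"
    if fmt not in ("pairs", "gmt"):
        raise InputFormatError(f"unknown association format {fmt!r}")

    groups: dict[str, set[str]] = {}
    if fmt == "gmt":
        for i, line in enumerate(lines, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"malformed GMT line {i}: expected >=3 fields")
            name = parts[0].strip()
            members = {normalize_mirna(m) for m in parts[2:] if m.strip()}
            if not members:
                raise InputFormatError(f"GMT group {name!r} has no members (line {i})")
            groups.setdefault(name, set()).update(members)
    else:
        delim = _sniff_delimiter(lines[0])
        start = 0
        first = [p.strip().lower() for p in lines[0].split(delim)]
        if first == ["disease", "mirna"]:  # optional header row
            start = 1
        for i, line in enumerate(lines[start:], start + 1):
            parts = [p for p in line.split(delim)]
            if len(parts) != 2:
                raise InputFormatError(
                    f"malformed association line {i}: expected 2 columns, got {len(parts)}"
                )
            disease, mirna = parts[0].strip(), normalize_mirna(parts[1])
            if not disease or not mirna:
                raise InputFormatError(f"empty field on association line {i}")
            groups.setdefault(disease, set()).add(mirna)
        if not groups:
            raise InputFormatError(f"no associations parsed from {path}")

    return GroupTable(groups={k: frozenset(v) for k, v in groups.items()})


def write_expression(ds: ExpressionDataset, path: str | Path, label_field: str = "class") -> Path:
    """Write an expression dataset as a TSV readable by :func:`read_expression`."""
    path = Path(path)
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_ids)
    df.insert(0, label_field, ds.labels)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def write_associations(groups: GroupTable, path: str | Path) -> Path:
    """Write a group table as a two-column (disease, miRNA) TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for disease in sorted(groups.groups):
            for mirna in sorted(groups.groups[disease]):
                fh.write(f"{disease}\t{mirna}\n")
    return path


_FLOAT_FMT = "%.6g"


def write_tables(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write pipeline outputs as headed TSV files with deterministic row order.

    Produces per-iteration group scores, the mean cumulative performance
    table (descending k), and the aggregated disease and miRNA lists.
    Returns a mapping from logical table name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    score_rows = [
        {"iteration": it.index, "disease": gs.group, "score": gs.score, "rank": gs.rank}
        for it in bundle.iterations
        for gs in it.scores
    ]
    score_df = pd.DataFrame(score_rows, columns=["iteration", "disease", "score", "rank"])
    paths["group_scores"] = outdir / "group_scores.tsv"
    score_df.to_csv(paths["group_scores"], sep="\t", index=False, float_format=_FLOAT_FMT)

    cum_rows = [
        {
            "#Groups": c.k,
            "#miRNAs": c.n_mirnas,
            "Accuracy": c.accuracy,
            "Sensitivity": c.sensitivity,
            "Specificity": c.specificity,
            "AUC": c.auc,
        }
        for c in sorted(bundle.cumulative_mean, key=lambda c: -c.k)
    ]
    cum_df = pd.DataFrame(
        cum_rows,
        columns=["#Groups", "#miRNAs", "Accuracy", "Sensitivity", "Specificity", "AUC"],
    )
    paths["cumulative_mean"] = outdir / "cumulative_mean.tsv"
    cum_df.to_csv(paths["cumulative_mean"], sep="\t", index=False, float_format=_FLOAT_FMT)

    for key, results in (("diseases", bundle.disease_results), ("mirnas", bundle.mirna_results)):
        rows = [
            {
                "entity": r.entity,
                "rho": r.rho,
                "p_value": r.p_value,
                "aggregate_rank": r.aggregate_rank,
            }
            for r in results
        ]
        df = pd.DataFrame(rows, columns=["entity", "rho", "p_value", "aggregate_rank"])
        paths[f"aggregated_{key}"] = outdir / f"aggregated_{key}.tsv"
        df.to_csv(paths[f"aggregated_{key}"], sep="\t", index=False, float_format=_FLOAT_FMT)

    return paths
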