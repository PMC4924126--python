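"""On-disk formats: feature tables (TSV/CSV) and selection lists (plain text).

The canonical table layout is a delimited text file with a header row of
``sample_id``, a label column, then one column per feature; one row per
sample.  Selection lists are plain text: ``#``-prefixed header lines naming
the method, dataset and intended size, then one feature name per line in
rank order (most-preferred first).  All writers are deterministic: stable
column order and a fixed ``%.6g`` float format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .table import LABELS, NEGATIVE, POSITIVE, FeatureTable, TableError

METHODS = ("LIG", "HIG", "RFS", "RFC", "SFC", "HIC", "ZNF", "PCF", "COMBINED")

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised on malformed on-disk input."""


@dataclass
class SelectionResult:
    """An ordered feature selection produced by one method on one dataset."""

    method: str
    dataset_id: str
    features: list[str]
    scores: Optional[list[float]] = None
    m: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise FormatError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if len(set(self.features)) != len(self.features):
            raise FormatError("selection contains duplicate features")
        if self.scores is not None and len(self.scores) != len(self.features):
            raise FormatError(
                f"{len(self.scores)} scores for {len(self.features)} features"
            )
        if self.m == 0:
            self.m = len(self.features)

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a table as TSV: header ``sample_id, label, <features>``."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_feature_table(
    path: str | os.PathLike,
    label_column: str = "label",
    positive_label: str = POSITIVE,
    negative_label: str = NEGATIVE,
    dialect: str = "tsv",
    provenance: Optional[str] = None,
) -> FeatureTable:
    """Read and validate a delimited feature table.

    Label values must equal ``positive_label`` or ``negative_label``; they are
    normalized to the internal ``positive``/``negative`` vocabulary.  Errors
    carry row/column context.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line:
        raise FormatError(f"{path}: empty file or missing header")
    header = header_line.split(sep)
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate header names: {dupes}")
    if label_column not in header:
        raise FormatError(f"{path}: missing label column {label_column!r}")

    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" in df.columns:
        sample_ids = df["sample_id"].tolist()
        df = df.drop(columns=["sample_id"])
    else:
        sample_ids = [f"s{i + 1}" for i in range(len(df))]

    raw_labels = df[label_column].tolist()
    df = df.drop(columns=[label_column])
    mapping = {positive_label: POSITIVE, negative_label: NEGATIVE}
    labels = []
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            raise FormatError(
                f"{path}: row {i + 2}: unknown label {lab!r} "
                f"(expected {positive_label!r} or {negative_label!r})"
            )
        labels.append(mapping[lab])

    values = np.empty((len(df), df.shape[1]), dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: column {col!r}, row {row}: non-numeric value "
                f"{bad.iloc[0]!r}" if len(bad) else f"{path}: column {col!r}: non-numeric"
            ) from None

    try:
        return FeatureTable(
            values=values,
            feature_names=list(df.columns),
            sample_ids=sample_ids,
            labels=np.array(labels, dtype=object),
            provenance=provenance if provenance is not None else os.path.basename(str(path)),
        )
    except TableError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection lists


def write_selection(sel: SelectionResult, path: str | os.PathLike) -> None:
    """Write a selection as commented plain text, one feature per line."""
    lines = [
        f"# method: {sel.method}",
        f"# dataset: {sel.dataset_id}",
        f"# m: {sel.m}",
    ]
    if sel.scores is not None:
        pairs = zip(sel.features, sel.scores)
        lines.extend(f"{f}\t{FLOAT_FORMAT % s}" for f, s in pairs)
    else:
        lines.extend(sel.features)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_selection(path: str | os.PathLike) -> SelectionResult:
    """Read a selection list written by :func:`write_selection`."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    raw = [line for line in raw if line.strip()]
    if not raw:
        raise FormatError(f"{path}: empty selection file")
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in raw:
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            if ":" not in text:
                raise FormatError(f"{path}: malformed header line {line!r}")
            key, _, val = text.partition(":")
            meta[key.strip()] = val.strip()
        else:
            body.append(line)
    for key in ("method", "dataset", "m"):
        if key not in meta:
            raise FormatError(f"{path}: missing header field {key!r}")
    features: list[str] = []
    scores: list[float] = []
    has_scores = body and "\t" in body[0]
    for line in body:
        parts = line.split("\t")
        features.append(parts[0])
        if has_scores:
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed scored line {line!r}")
            scores.append(float(parts[1]))
    if len(set(features)) != len(features):
        dupes = sorted({f for f in features if features.count(f) > 1})
        raise FormatError(f"{path}: duplicate feature lines: {dupes}")
    try:
        m = int(meta["m"])
    except ValueError:
        raise FormatError(f"{path}: non-integer m {meta['m']!r}") from None
    return SelectionResult(
        method=meta["method"],
        dataset_id=meta["dataset"],
        features=features,
        scores=scores if has_scores else None,
        m=m,
    )


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a planted-truth manifest (feature, role, block) as TSV."""
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t")
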