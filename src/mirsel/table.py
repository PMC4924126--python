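"""In-memory container for labeled feature tables.

A :class:`FeatureTable` is the universal currency of the pipeline: a dense
``n_samples x p`` matrix of numeric feature values with unique feature names,
unique sample ids, and a binary class label per sample.  The two label values
are normalized to ``"positive"`` (pre-miRNA / target class) and ``"negative"``
(pseudo hairpin / unknown class); the one-class path reinterprets ``negative``
as "unknown" at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)


class TableError(ValueError):
    """Raised when a feature table violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples x features numeric matrix with labels.

    Parameters
    ----------
    values
        ``(n_samples, p)`` float array; no missing values allowed.
    feature_names
        ``p`` unique strings naming the columns.
    sample_ids
        ``n_samples`` unique strings naming the rows.
    labels
        Per-sample class, each ``"positive"`` or ``"negative"``.
    provenance
        Free-text origin tag (a species code or ``"synthetic"``).
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise TableError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(self.sample_ids) != n:
            raise TableError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.labels) != n:
            raise TableError(f"{len(self.labels)} labels for {n} rows")
        if len(set(self.feature_names)) != p:
            dupes = _duplicates(self.feature_names)
            raise TableError(f"duplicate feature names: {dupes}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise TableError(f"duplicate sample ids: {dupes}")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise TableError(f"labels outside {LABELS}: {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise TableError("values contain NaN or infinite entries")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    # -- views -------------------------------------------------------------

    def restrict(self, features: list[str]) -> "FeatureTable":
        """Return a table keeping only ``features``, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in features if f not in index]
        if missing:
            raise TableError(f"features not in table: {missing}")
        cols = [index[f] for f in features]
        return FeatureTable(
            values=self.values[:, cols],
            feature_names=list(features),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            provenance=self.provenance,
        )

    def subset_rows(self, row_idx: np.ndarray) -> "FeatureTable":
        row_idx = np.asarray(row_idx)
        return FeatureTable(
            values=self.values[row_idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in row_idx],
            labels=self.labels[row_idx],
            provenance=self.provenance,
        )

    def only_class(self, label: str) -> "FeatureTable":
        return self.subset_rows(np.flatnonzero(self.label_mask(label)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def concat_tables(tables: list[FeatureTable], provenance: str = "combined") -> FeatureTable:
    """Stack tables sharing the same feature space (row-wise)."""
    if not tables:
        raise TableError("no tables to concatenate")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise TableError("tables do not share an identical feature space")
    return FeatureTable(
        values=np.vstack([t.values for t in tables]),
        feature_names=list(names),
        sample_ids=[s for t in tables for s in t.sample_ids],
        labels=np.concatenate([t.labels for t in tables]),
        provenance=provenance,
    )


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out
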