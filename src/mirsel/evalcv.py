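"""Monte-Carlo cross-validation, negative injection, and SE/SP/ACC summaries.

The one-class protocol repeatedly (default 100x) samples 90% of the positive
rows for training and tests on the held-out 10% plus *all* negative rows,
which are injected as the unknown class — they never enter training.  The
two-class protocol repeatedly (default 10x) draws a stratified 90/10 split
of the combined dataset.  Per fold a confusion matrix is recorded
(positives are the target class); folds aggregate to mean and standard
deviation of sensitivity, specificity, pooled accuracy and balanced
accuracy.

Because every one-class fold pits ~10% of the positives against the full
negative set, pooled accuracy is dominated by the negatives; balanced
accuracy (SE+SP)/2 is therefore the headline number, with pooled accuracy
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import (
    OCCConfig,
    SVMConfig,
    TARGET,
    fit_occ,
    fit_tcc,
    predict_occ,
    predict_tcc,
)
from .table import NEGATIVE, POSITIVE, FeatureTable, concat_tables
from .tablio import SelectionResult


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class CVConfig:
    """Monte-Carlo cross-validation parameters (repetitions and split)."""

    folds_occ: int = 100
    folds_tcc: int = 10
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds_occ < 1 or self.folds_tcc < 1:
            raise EvalError("fold counts must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise EvalError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class FoldResult:
    """Confusion counts of one fold; positives are the target class."""

    fold: int
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise EvalError("confusion counts must be >= 0")


def compute_metrics(fr: FoldResult) -> tuple[float, float, float, float]:
    """(SE, SP, pooled ACC, balanced ACC) from one fold's confusion counts."""
    n_pos = fr.tp + fr.fn
    n_neg = fr.tn + fr.fp
    if n_pos < 1 or n_neg < 1:
        raise EvalError("both classes must be present in the test set")
    se = fr.tp / n_pos
    sp = fr.tn / n_neg
    acc_pooled = (fr.tp + fr.tn) / (n_pos + n_neg)
    acc_balanced = (se + sp) / 2.0
    return se, sp, acc_pooled, acc_balanced


@dataclass
class MetricSummary:
    """Per-fold confusion counts with mean/sd SE, SP and accuracies."""

    folds: list[FoldResult]
    se: float
    sp: float
    acc_pooled: float
    acc_balanced: float
    sd_se: float
    sd_sp: float
    sd_acc_pooled: float
    sd_acc_balanced: float
    method: str = ""
    dataset_id: str = ""
    learner: str = ""

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def to_row(self) -> dict:
        return {
            "dataset": self.dataset_id,
            "method": self.method,
            "learner": self.learner,
            "n_folds": self.n_folds,
            "SE": self.se,
            "SP": self.sp,
            "ACC_pooled": self.acc_pooled,
            "ACC_balanced": self.acc_balanced,
            "sd_SE": self.sd_se,
            "sd_SP": self.sd_sp,
            "sd_ACC_pooled": self.sd_acc_pooled,
            "sd_ACC_balanced": self.sd_acc_balanced,
        }


def aggregate(
    folds: list[FoldResult],
    method: str = "",
    dataset_id: str = "",
    learner: str = "",
) -> MetricSummary:
    """Mean and sample standard deviation (n-1) of per-fold metrics."""
    if not folds:
        raise EvalError("no folds to aggregate")
    per_fold = np.array([compute_metrics(fr) for fr in folds])
    means = per_fold.mean(axis=0)
    if len(folds) > 1:
        sds = per_fold.std(axis=0, ddof=1)
    else:
        sds = np.zeros(4)
    return MetricSummary(
        folds=list(folds),
        se=float(means[0]),
        sp=float(means[1]),
        acc_pooled=float(means[2]),
        acc_balanced=float(means[3]),
        sd_se=float(sds[0]),
        sd_sp=float(sds[1]),
        sd_acc_pooled=float(sds[2]),
        sd_acc_balanced=float(sds[3]),
        method=method,
        dataset_id=dataset_id,
        learner=learner,
    )


# ---------------------------------------------------------------------------
# splitting


def split_mc(
    n: int, train_fraction: float, fold_seed
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random train/test index split, at least one sample each side."""
    if n < 2:
        raise EvalError(f"need >= 2 samples to split, got {n}")
    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return perm[:n_train], perm[n_train:]


def _fold_rng(seed: int, fold: int) -> np.random.Generator:
    # fold streams derive from (seed, fold) so any fold reruns in isolation
    return np.random.default_rng([seed, fold])


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation protocols


def mccv_occ(
    positives: FeatureTable,
    negatives: FeatureTable,
    selection: SelectionResult,
    cv: CVConfig,
    occ: OCCConfig,
) -> MetricSummary:
    """One-class MCCV with full negative injection at test time.

    Each fold trains on ~90% of the positives (restricted to the selected
    features) and tests on the held-out positives plus every negative row.
    """
    pos = positives.only_class(POSITIVE).restrict(selection.features)
    neg = negatives.only_class(NEGATIVE).restrict(selection.features)
    if pos.n_samples < 2:
        raise EvalError("need >= 2 positive samples")
    folds = []
    for f in range(cv.folds_occ):
        rng = _fold_rng(cv.seed, f)
        train_idx, test_idx = split_mc(pos.n_samples, cv.train_fraction, rng)
        fold_occ = OCCConfig(
            occ.k_occ,
            occ.threshold_quantile,
            int(rng.integers(2**31)),
            occ.calibration_fraction,
        )
        model = fit_occ(pos.subset_rows(train_idx), fold_occ)
        pred_pos = predict_occ(model, pos.subset_rows(test_idx))
        pred_neg = predict_occ(model, neg)
        tp = int((pred_pos == TARGET).sum())
        fn = len(pred_pos) - tp
        fp = int((pred_neg == TARGET).sum())
        tn = len(pred_neg) - fp
        folds.append(FoldResult(f, tp, fn, tn, fp))
    return aggregate(
        folds, method=selection.method, dataset_id=positives.provenance, learner="OCC"
    )


def mccv_tcc(
    all_data: FeatureTable,
    selection: SelectionResult,
    cv: CVConfig,
    svm: SVMConfig,
) -> MetricSummary:
    """Two-class MCCV with per-class (stratified) 90/10 splits."""
    data = all_data.restrict(selection.features)
    pos_idx = np.flatnonzero(data.label_mask(POSITIVE))
    neg_idx = np.flatnonzero(data.label_mask(NEGATIVE))
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise EvalError("need >= 2 samples per class for two-class MCCV")
    folds = []
    for f in range(cv.folds_tcc):
        rng = _fold_rng(cv.seed, f)
        p_tr, p_te = split_mc(len(pos_idx), cv.train_fraction, rng)
        n_tr, n_te = split_mc(len(neg_idx), cv.train_fraction, rng)
        train = data.subset_rows(np.concatenate([pos_idx[p_tr], neg_idx[n_tr]]))
        test = data.subset_rows(np.concatenate([pos_idx[p_te], neg_idx[n_te]]))
        model = fit_tcc(train, svm)
        pred = predict_tcc(model, test)
        is_pos = test.label_mask(POSITIVE)
        tp = int((pred[is_pos] == POSITIVE).sum())
        fn = int(is_pos.sum()) - tp
        fp = int((pred[~is_pos] == POSITIVE).sum())
        tn = int((~is_pos).sum()) - fp
        folds.append(FoldResult(f, tp, fn, tn, fp))
    return aggregate(
        folds, method=selection.method, dataset_id=all_data.provenance, learner="TCC"
    )


# ---------------------------------------------------------------------------
# TCC - OCC comparison


def summaries_frame(summaries: list[MetricSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def difference_table(
    occ_results: list[MetricSummary],
    tcc_results: list[MetricSummary],
    metric: str = "acc_balanced",
) -> pd.DataFrame:
    """TCC accuracy minus OCC accuracy per (dataset, method).

    Rows are datasets plus an ``Average`` row; method columns are ordered by
    increasing average difference.  Positive cells mean the two-class model
    outperformed the one-class model.
    """
    if metric not in ("acc_balanced", "acc_pooled"):
        raise EvalError(f"unknown metric {metric!r}")
    occ = {(s.dataset_id, s.method): getattr(s, metric) for s in occ_results}
    tcc = {(s.dataset_id, s.method): getattr(s, metric) for s in tcc_results}
    if set(occ) != set(tcc):
        missing = set(occ) ^ set(tcc)
        raise EvalError(f"OCC/TCC result keys do not match: {sorted(missing)}")
    datasets = sorted({k[0] for k in occ})
    methods = sorted({k[1] for k in occ})
    data = {
        m: [tcc[(d, m)] - occ[(d, m)] for d in datasets] for m in methods
    }
    df = pd.DataFrame(data, index=datasets)
    df.loc["Average"] = df.mean(axis=0)
    order = df.loc["Average"].sort_values(kind="stable").index.tolist()
    return df[order]
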