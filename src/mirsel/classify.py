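"""The two learners: a k-means one-class classifier and an RBF two-class SVM.

One-class classification (OCC) trains on positive (target) examples only:
k-means centroids summarize the target class in min-max-normalized feature
space, and a sample is accepted as ``target`` when its distance to the
nearest centroid does not exceed a threshold ``tau``.  Everything farther is
rejected as ``unknown``.  The radius ``tau`` is calibrated so that both of
the model's coverage contracts hold at the configured quantile ``q``:

* at least ``ceil(q * n)`` of the training rows fall inside ``tau``
  (in-sample quantile with "higher" interpolation), and
* a *new* target-class sample falls inside ``tau`` with probability at
  least ``q`` (split-conformal quantile of nearest-centroid distances on a
  held-out calibration fraction of the training rows — an in-sample
  quantile alone systematically under-covers new data).

``tau`` is the larger of the two candidate radii.

Two-class classification (TCC) is a soft-margin SVM with RBF kernel
``exp(-gamma * ||u - v||^2)``, gamma 0.7 and cost 4.0 by default, trained on
min-max-normalized features of both classes.

Both learners are pure functions of (training data, config, seed); trained
models serialize to versioned JSON flat files and round-trip exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .table import NEGATIVE, POSITIVE, FeatureTable

TARGET = "target"
UNKNOWN = "unknown"

_FORMAT_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class OCCConfig:
    """One-class learner parameters.

    ``k_occ`` centroids describe the target class; ``threshold_quantile``
    sets the nominal target-class acceptance rate of the rejection radius.
    Defaults (5 centroids, 0.95) accept ~95% of target samples while keeping
    the boundary tight around the target class.  ``calibration_fraction`` of
    the training rows are held out of the centroid fit to calibrate the
    radius on unseen data.
    """

    k_occ: int = 5
    threshold_quantile: float = 0.95
    seed: int = 0
    calibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.k_occ < 1:
            raise ModelError(f"k_occ must be >= 1, got {self.k_occ}")
        if not 0.0 < self.threshold_quantile <= 1.0:
            raise ModelError(
                f"threshold_quantile must be in (0, 1], got {self.threshold_quantile}"
            )
        if not 0.0 <= self.calibration_fraction < 1.0:
            raise ModelError(
                f"calibration_fraction must be in [0, 1), got {self.calibration_fraction}"
            )


@dataclass(frozen=True)
class SVMConfig:
    """Two-class RBF-SVM parameters (kernel width gamma, soft-margin cost)."""

    gamma: float = 0.7
    cost: float = 4.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ModelError(f"gamma must be > 0, got {self.gamma}")
        if self.cost <= 0:
            raise ModelError(f"cost must be > 0, got {self.cost}")


# ---------------------------------------------------------------------------
# min-max normalization


@dataclass
class NormParams:
    """Per-feature training min/max for [0, 1] scaling."""

    min_: np.ndarray
    max_: np.ndarray

    @property
    def identity(self) -> bool:
        return self.min_.size == 0


def minmax_fit(train_values: np.ndarray) -> NormParams:
    train_values = np.asarray(train_values, dtype=float)
    if train_values.ndim != 2 or train_values.shape[0] < 1:
        raise ModelError("minmax_fit needs at least one training row")
    return NormParams(train_values.min(axis=0), train_values.max(axis=0))


def minmax_apply(params: NormParams, values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] with training bounds; constant features map to 0.0,
    out-of-range test values are clipped."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != params.min_.shape[0]:
        raise ModelError(
            f"dimension mismatch: {values.shape[-1]} columns vs "
            f"{params.min_.shape[0]} fitted features"
        )
    span = params.max_ - params.min_
    out = np.zeros_like(values, dtype=float)
    ok = span > 0
    out[..., ok] = (values[..., ok] - params.min_[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


def _as_matrix(samples: "FeatureTable | np.ndarray", features: list[str]) -> np.ndarray:
    if isinstance(samples, FeatureTable):
        return samples.restrict(features).values
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(features):
        raise ModelError(
            f"expected {len(features)} feature columns, got {arr.shape[1]}"
        )
    return arr


# ---------------------------------------------------------------------------
# one-class classifier


@dataclass
class OCCModel:
    """Trained one-class model: centroids + rejection radius in [0,1] space."""

    centroids: np.ndarray
    tau: float
    norm: NormParams
    selected_features: list[str]
    config: OCCConfig

    def nearest_distance(self, values: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(values[:, None, :] - self.centroids[None, :, :], axis=2)
        return d.min(axis=1)

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "format": "mirsel-occ",
            "version": _FORMAT_VERSION,
            "selected_features": self.selected_features,
            "norm_min": self.norm.min_.tolist(),
            "norm_max": self.norm.max_.tolist(),
            "centroids": self.centroids.tolist(),
            "tau": self.tau,
            "k_occ": self.config.k_occ,
            "threshold_quantile": self.config.threshold_quantile,
            "seed": self.config.seed,
            "calibration_fraction": self.config.calibration_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "OCCModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "mirsel-occ":
            raise ModelError(f"{path}: not a one-class model file")
        return cls(
            centroids=np.array(d["centroids"], dtype=float),
            tau=float(d["tau"]),
            norm=NormParams(
                np.array(d["norm_min"], dtype=float),
                np.array(d["norm_max"], dtype=float),
            ),
            selected_features=list(d["selected_features"]),
            config=OCCConfig(
                d["k_occ"],
                d["threshold_quantile"],
                d["seed"],
                d.get("calibration_fraction", 0.2),
            ),
        )


def fit_occ(
    positives: FeatureTable,
    cfg: OCCConfig,
    features: Optional[Sequence[str]] = None,
) -> OCCModel:
    """Fit the one-class model on positive rows only.

    Min-max normalization is fitted on the positive training rows.  A
    ``calibration_fraction`` of the rows is held out (seeded); k-means
    (seeded, 10 restarts, best within-cluster sum of squares) places
    ``k_occ`` centroids on the remainder.  The rejection radius ``tau`` is
    the larger of

    * the ``threshold_quantile`` in-sample quantile ("higher" interpolation)
      of all training rows' nearest-centroid distances, covering at least
      ``ceil(q*n)`` training rows, and
    * the split-conformal quantile (rank ``ceil(q*(n_cal+1))``) of the
      held-out calibration distances, so a new target-class sample is
      accepted with probability at least ``q``.
    """
    feats = list(features) if features is not None else list(positives.feature_names)
    if NEGATIVE in set(positives.labels):
        positives = positives.only_class(POSITIVE)
    X_raw = positives.restrict(feats).values
    n = X_raw.shape[0]
    if n < cfg.k_occ:
        raise ModelError(f"{n} positive rows < k_occ={cfg.k_occ}")
    norm = minmax_fit(X_raw)
    X = minmax_apply(norm, X_raw)

    rng = np.random.default_rng(cfg.seed)
    n_cal = max(min(int(cfg.calibration_fraction * n), n - cfg.k_occ), 0)
    perm = rng.permutation(n)
    cal_idx, fit_idx = perm[:n_cal], perm[n_cal:]

    km = KMeans(
        n_clusters=cfg.k_occ,
        n_init=10,
        random_state=cfg.seed % (2**32),
        algorithm="lloyd",
    ).fit(X[fit_idx])
    model = OCCModel(
        centroids=km.cluster_centers_,
        tau=0.0,
        norm=norm,
        selected_features=feats,
        config=cfg,
    )
    q = cfg.threshold_quantile
    tau = float(np.quantile(model.nearest_distance(X), q, method="higher"))
    if n_cal > 0:
        d_cal = np.sort(model.nearest_distance(X[cal_idx]))
        rank = int(np.ceil(q * (n_cal + 1)))
        # rank beyond the calibration set degrades to its maximum distance
        tau = max(tau, float(d_cal[min(rank, n_cal) - 1]))
    model.tau = tau
    return model


def predict_occ(model: OCCModel, samples: "FeatureTable | np.ndarray") -> np.ndarray:
    """Label samples ``target`` within tau of a centroid, else ``unknown``."""
    X = minmax_apply(model.norm, _as_matrix(samples, model.selected_features))
    d = model.nearest_distance(X)
    return np.where(d <= model.tau, TARGET, UNKNOWN).astype(object)


# ---------------------------------------------------------------------------
# two-class classifier


@dataclass
class TCCModel:
    """Trained RBF-SVM state: support vectors, dual coefficients, intercept.

    The decision function is evaluated directly from the stored arrays, so a
    saved and reloaded model predicts identically.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: list[str]  # [negative_label, positive_label] decision order
    norm: Optional[NormParams]
    selected_features: list[str]
    config: SVMConfig

    def decision_function(self, samples: "FeatureTable | np.ndarray") -> np.ndarray:
        X = _as_matrix(samples, self.selected_features)
        if self.norm is not None:
            X = minmax_apply(self.norm, X)
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.config.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "format": "mirsel-tcc",
            "version": _FORMAT_VERSION,
            "selected_features": self.selected_features,
            "norm_min": None if self.norm is None else self.norm.min_.tolist(),
            "norm_max": None if self.norm is None else self.norm.max_.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "classes": self.classes,
            "gamma": self.config.gamma,
            "cost": self.config.cost,
            "normalize": self.config.normalize,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TCCModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "mirsel-tcc":
            raise ModelError(f"{path}: not a two-class model file")
        norm = None
        if d["norm_min"] is not None:
            norm = NormParams(
                np.array(d["norm_min"], dtype=float),
                np.array(d["norm_max"], dtype=float),
            )
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            classes=list(d["classes"]),
            norm=norm,
            selected_features=list(d["selected_features"]),
            config=SVMConfig(d["gamma"], d["cost"], d["normalize"]),
        )


def fit_tcc(
    train: FeatureTable,
    cfg: SVMConfig,
    features: Optional[Sequence[str]] = None,
) -> TCCModel:
    """Fit the RBF SVM on both classes (min-max normalized when configured)."""
    feats = list(features) if features is not None else list(train.feature_names)
    sub = train.restrict(feats)
    classes = set(sub.labels)
    if classes != {POSITIVE, NEGATIVE}:
        raise ModelError(
            f"two-class training requires both classes, got {sorted(classes)}"
        )
    X = sub.values
    norm = None
    if cfg.normalize:
        norm = minmax_fit(X)
        X = minmax_apply(norm, X)
    y = np.asarray(sub.labels, dtype=object)
    svc = SVC(C=cfg.cost, gamma=cfg.gamma, kernel="rbf").fit(X, y)
    # classes_ is sorted: ['negative', 'positive']; decision > 0 -> classes_[1]
    return TCCModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        classes=[str(c) for c in svc.classes_],
        norm=norm,
        selected_features=feats,
        config=cfg,
    )


def predict_tcc(model: TCCModel, samples: "FeatureTable | np.ndarray") -> np.ndarray:
    """Deterministic labels from the fitted decision function."""
    df = model.decision_function(samples)
    return np.where(df > 0, model.classes[1], model.classes[0]).astype(object)
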