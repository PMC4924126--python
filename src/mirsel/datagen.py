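"""Synthetic pre-miRNA-like feature tables with planted structure.

Real pre-miRNA benchmarks parameterize hairpin sequences with >1,000
sequence/structure features and contrast a few hundred positive precursors
per species against 980 pseudo hairpins.  This module emulates the
*statistical* shape of such tables without touching RNA: a small subset of
strongly class-shifted (informative) columns, a subset of weakly shifted
columns, blocks of mutually correlated (redundant) columns, zero-inflated
sparse columns, and pure noise.  Every generated table comes with a planted
truth manifest mapping each column to its role, which downstream tests use
as an oracle.

Generation is a pure function of the configuration: the same
:class:`SynthConfig` always produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table import NEGATIVE, POSITIVE, FeatureTable

ROLE_INFORMATIVE = "informative"
ROLE_WEAK = "weak"
ROLE_REDUNDANT = "redundant"
ROLE_SPARSE = "sparse"
ROLE_NOISE = "noise"


class ConfigError(ValueError):
    """Raised when a generator configuration violates an invariant."""


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic feature-table generator.

    Defaults emulate one species-scale dataset: several hundred positives
    against 980 negatives over ~1,000 features, of which only a small subset
    carries class signal.

    Parameters
    ----------
    n_pos, n_neg
        Positive / negative sample counts.  The negative default of 980
        matches the size of the pseudo-hairpin reference set this generator
        stands in for.
    p
        Total feature count.
    n_informative, n_weak
        Columns whose positive-class mean is shifted by ``effect_strong``
        (resp. ``effect_weak``) pooled standard deviations.
    n_redundant_blocks, block_size, within_block_corr
        Blocks of mutually correlated columns driven by a shared latent
        variable; pairwise Pearson correlation inside a block is calibrated
        to ``within_block_corr``.
    effect_strong, effect_weak
        Standardized mean shifts (Cohen's d) of informative / weak columns.
    zero_inflation
        Fraction of columns that are zero-inflated (sparse).
    zero_prob
        Per-entry probability of an exact 0.0 in a sparse column.
    seed
        Seed for all randomness, including role placement.
    """

    n_pos: int = 400
    n_neg: int = 980
    p: int = 1000
    n_informative: int = 30
    n_weak: int = 60
    n_redundant_blocks: int = 20
    block_size: int = 5
    within_block_corr: float = 0.9
    effect_strong: float = 1.5
    effect_weak: float = 0.3
    zero_inflation: float = 0.10
    zero_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "p": self.p,
            "n_informative": self.n_informative,
            "n_weak": self.n_weak,
            "n_redundant_blocks": self.n_redundant_blocks,
            "block_size": self.block_size,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.within_block_corr <= 1.0:
            raise ConfigError(
                f"within_block_corr must be in [0, 1], got {self.within_block_corr}"
            )
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigError(
                f"zero_inflation must be in [0, 1], got {self.zero_inflation}"
            )
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ConfigError(f"zero_prob must be in [0, 1], got {self.zero_prob}")
        planted = (
            self.n_informative
            + self.n_weak
            + self.n_redundant_blocks * self.block_size
        )
        n_sparse = int(round(self.zero_inflation * self.p))
        if planted + n_sparse > self.p:
            raise ConfigError(
                f"planted columns ({planted} shifted/redundant + {n_sparse} sparse) "
                f"exceed p={self.p}"
            )


def feature_names(p: int) -> list[str]:
    width = max(4, len(str(p)))
    return [f"f{i + 1:0{width}d}" for i in range(p)]


def planted_truth(config: SynthConfig) -> pd.DataFrame:
    """Deterministic column-role manifest implied by ``config``.

    Returns a frame with columns ``feature``, ``role`` and ``block``
    (block id for redundant columns, -1 otherwise).  Roles partition all
    ``p`` columns; placement depends only on ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    names = feature_names(config.p)
    order = rng.permutation(config.p)

    roles = np.full(config.p, ROLE_NOISE, dtype=object)
    blocks = np.full(config.p, -1, dtype=int)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor : cursor + k]
        cursor += k
        return idx

    roles[take(config.n_informative)] = ROLE_INFORMATIVE
    roles[take(config.n_weak)] = ROLE_WEAK
    for b in range(config.n_redundant_blocks):
        idx = take(config.block_size)
        roles[idx] = ROLE_REDUNDANT
        blocks[idx] = b
    n_sparse = int(round(config.zero_inflation * config.p))
    roles[take(n_sparse)] = ROLE_SPARSE

    return pd.DataFrame({"feature": names, "role": roles, "block": blocks})


def _column_affine(config: SynthConfig, manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-column scale/shift making raw ranges heterogeneous.

    Drawn from the structural stream so every table generated under the same
    seed shares the same column geometry.  Sparse columns are scaled but not
    shifted, preserving exact zeros.
    """
    rng = np.random.default_rng([config.seed, 0, 1])
    scale = rng.uniform(0.5, 3.0, size=config.p)
    shift = rng.uniform(-2.0, 5.0, size=config.p)
    shift[(manifest["role"] == ROLE_SPARSE).to_numpy()] = 0.0
    return scale, shift


def _draw_values(
    config: SynthConfig,
    manifest: pd.DataFrame,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a value matrix for ``labels`` under the planted column roles."""
    n = len(labels)
    pos = labels == POSITIVE
    roles = manifest["role"].to_numpy()
    blocks = manifest["block"].to_numpy()

    values = rng.standard_normal((n, config.p))

    for role, delta in ((ROLE_INFORMATIVE, config.effect_strong), (ROLE_WEAK, config.effect_weak)):
        cols = np.flatnonzero(roles == role)
        if cols.size:
            values[np.ix_(pos, cols)] += delta

    # Redundant blocks: latent driver z shared inside a block; each member is
    # sqrt(r)*z + sqrt(1-r)*eps, giving pairwise Pearson correlation r.
    r = config.within_block_corr
    a, b = np.sqrt(r), np.sqrt(1.0 - r)
    for blk in range(config.n_redundant_blocks):
        cols = np.flatnonzero(blocks == blk)
        if cols.size == 0:
            continue
        driver = rng.standard_normal(n)
        values[:, cols] = a * driver[:, None] + b * rng.standard_normal((n, cols.size))

    # Sparse columns: positive-leaning magnitudes punctured by exact zeros.
    sparse_cols = np.flatnonzero(roles == ROLE_SPARSE)
    if sparse_cols.size:
        base = np.abs(rng.normal(1.0, 1.0, size=(n, sparse_cols.size))) + 0.1
        mask = rng.random((n, sparse_cols.size)) < config.zero_prob
        base[mask] = 0.0
        values[:, sparse_cols] = base

    scale, shift = _column_affine(config, manifest)
    return values * scale + shift


def generate_feature_table(
    config: SynthConfig,
    provenance: str = "synthetic",
    _stream: int = 1,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate one labeled table plus its planted-truth manifest.

    Rows are ``n_pos`` positives followed by ``n_neg`` negatives.  The value
    draw uses the sub-stream ``(seed, _stream)``; the default stream yields
    the canonical table for the configuration, while :func:`generate_study`
    uses distinct streams to produce independent tables over the same planted
    column structure.
    """
    config.validate()
    if config.n_pos < 2 or config.n_neg < 2:
        raise ConfigError("need at least 2 samples per class")
    if config.p < 1:
        raise ConfigError("p must be >= 1")
    manifest = planted_truth(config)
    labels = np.array(
        [POSITIVE] * config.n_pos + [NEGATIVE] * config.n_neg, dtype=object
    )
    rng = np.random.default_rng([config.seed, _stream])
    values = _draw_values(config, manifest, labels, rng)
    ids = [f"{provenance}_s{i + 1:05d}" for i in range(len(labels))]
    table = FeatureTable(values, feature_names(config.p), ids, labels, provenance)
    return table, manifest


@dataclass(frozen=True)
class StudyConfig:
    """A multi-dataset benchmark: several positive sets sharing one negative set.

    Mirrors a study design of seven species-specific positive collections
    evaluated against a single shared set of 980 pseudo hairpins.  Positive
    sample sizes vary per dataset, drawn once (seeded) from
    ``[n_pos_min, n_pos_max]``.
    """

    base: SynthConfig = field(default_factory=SynthConfig)
    n_datasets: int = 7
    n_pos_min: int = 200
    n_pos_max: int = 600


def generate_study(
    study: StudyConfig,
) -> tuple[dict[str, FeatureTable], FeatureTable, pd.DataFrame]:
    """Generate per-dataset positive tables and one shared negative table.

    All tables share the feature space and planted column roles of
    ``study.base`` (same seed, same manifest); values are drawn independently
    per dataset.  Returns ``(positives_by_dataset, negatives, manifest)``
    where each positives table contains only positive rows and the negatives
    table only negative rows.
    """
    cfg = study.base
    cfg.validate()
    if study.n_datasets < 1:
        raise ConfigError("n_datasets must be >= 1")
    if not 2 <= study.n_pos_min <= study.n_pos_max:
        raise ConfigError("need 2 <= n_pos_min <= n_pos_max")
    manifest = planted_truth(cfg)
    size_rng = np.random.default_rng([cfg.seed, 0, 2])
    sizes = size_rng.integers(study.n_pos_min, study.n_pos_max + 1, study.n_datasets)

    positives: dict[str, FeatureTable] = {}
    for i in range(study.n_datasets):
        name = f"sp{i + 1}"
        n_pos = int(sizes[i])
        labels = np.array([POSITIVE] * n_pos, dtype=object)
        rng = np.random.default_rng([cfg.seed, 10 + i])
        values = _draw_values(cfg, manifest, labels, rng)
        ids = [f"{name}_s{j + 1:05d}" for j in range(n_pos)]
        positives[name] = FeatureTable(
            values, feature_names(cfg.p), ids, labels, provenance=name
        )

    neg_labels = np.array([NEGATIVE] * cfg.n_neg, dtype=object)
    rng = np.random.default_rng([cfg.seed, 9])
    neg_values = _draw_values(cfg, manifest, neg_labels, rng)
    neg_ids = [f"neg_s{j + 1:05d}" for j in range(cfg.n_neg)]
    negatives = FeatureTable(
        neg_values, feature_names(cfg.p), neg_ids, neg_labels, provenance="negatives"
    )
    return positives, negatives, manifest
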