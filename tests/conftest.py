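import numpy as np
import pytest

from mirsel.datagen import SynthConfig, generate_feature_table
from mirsel.table import FeatureTable


@pytest.fixture
def toy_table() -> FeatureTable:
    """Six samples, four handcrafted features: a label copy, a constant,
    a noisy column and a zero-bearing column."""
    values = np.array(
        [
            [1.0, 5.0, 0.3, 1.0],
            [1.0, 5.0, -0.8, 2.0],
            [1.0, 5.0, 0.1, 3.0],
            [0.0, 5.0, 0.5, 0.0],
            [0.0, 5.0, -0.2, 4.0],
            [0.0, 5.0, 0.9, 5.0],
        ]
    )
    return FeatureTable(
        values=values,
        feature_names=["label_copy", "const", "noise", "zeroish"],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=np.array(["positive"] * 3 + ["negative"] * 3, dtype=object),
        provenance="toy",
    )


@pytest.fixture(scope="session")
def planted_500():
    """Session-wide synthetic table: 250+250 samples, 500 features,
    20 informative columns at effect size 1.5 (seed 7)."""
    cfg = SynthConfig(
        n_pos=250, n_neg=250, p=500, n_informative=20,
        effect_strong=1.5, effect_weak=0.3, seed=7,
    )
    table, manifest = generate_feature_table(cfg)
    return cfg, table, manifest


def make_blob_table(
    n_pos: int = 60,
    n_neg: int = 60,
    n_features: int = 5,
    shift: float = 6.0,
    seed: int = 0,
    prefix: str = "b",
) -> FeatureTable:
    """Two well-separated Gaussian blobs, positives shifted by ``shift``."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(shift, 1.0, size=(n_pos, n_features))
    neg = rng.normal(0.0, 1.0, size=(n_neg, n_features))
    return FeatureTable(
        values=np.vstack([pos, neg]),
        feature_names=[f"g{j}" for j in range(n_features)],
        sample_ids=[f"{prefix}{i}" for i in range(n_pos + n_neg)],
        labels=np.array(["positive"] * n_pos + ["negative"] * n_neg, dtype=object),
        provenance="blobs",
    )
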