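import numpy as np
import pytest

from hepavote.synthetic import BlockSpec, GeneratorConfig, PlantedSignal, generate

#: backend overrides that shrink the boosters/forests for fast unit tests
FAST_HP = {
    "GDBT": {"n_estimators": 30},
    "AdaBT": {"n_estimators": 30},
    "XGBT": {"n_estimators": 30},
    "RF": {"n_estimators": 50},
    "ExtraTrees": {"n_estimators": 50},
    "LGBT": {"n_estimators": 30, "min_child_samples": 5},
    "CatBT": {"max_iter": 30},
}

TINY_SPECS = (
    BlockSpec("ExtendedFP", "binary", 16),
    BlockSpec("KRFP", "binary", 16),
    BlockSpec("AP2DFP", "binary", 8),
    BlockSpec("nKRFP", "count", 8),
)


def tiny_config(seed=0, **overrides):
    defaults = dict(
        n_compounds=80,
        block_specs=TINY_SPECS,
        signal={
            "ExtendedFP": PlantedSignal(3, 0.85, 0.15),
            "KRFP": PlantedSignal(3, 0.85, 0.15),
        },
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def fast_hp():
    return FAST_HP


@pytest.fixture(scope="session")
def tiny_dataset():
    """80 compounds, 4 tiny fingerprint blocks + descriptors, strong signal."""
    return generate(tiny_config(seed=11))


@pytest.fixture(scope="session")
def separable_toy():
    """20 points in 2-D, linearly separable by the first feature."""
    rng = np.random.default_rng(5)
    n = 20
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = np.column_stack([y * 4.0 - 2.0 + rng.normal(0, 0.3, n), rng.normal(0, 1, n)])
    return X, y
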