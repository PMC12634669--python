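import numpy as np
import pandas as pd
import pytest

from agbstack.synthetic import SyntheticConfig, generate_dataset


def exact_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """Noise-free study conditions with group-constant growth: the whole
    back-casting chain is exact under this configuration."""
    kw = dict(
        n_plots=12,
        trees_per_plot=(80, 120),
        species_pool=(("Quercus", 0.5762), ("P.massoniana", 0.4476)),
        dbh_noise_sd_cm=0.0,
        group_increment_params=(0.3, 0.0),
        agb_noise_sd=0.0,
        raster_shape=(80, 80),
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def exact_dataset():
    return generate_dataset(exact_config())


@pytest.fixture(scope="session")
def noisy_dataset():
    """A small draw under the default noise levels (1 cm DBH noise)."""
    return generate_dataset(
        SyntheticConfig(n_plots=25, raster_shape=(100, 100), seed=11)
    )


@pytest.fixture(scope="session")
def small_feature_table():
    """A compact feature/target table with one strong linear signal."""
    rng = np.random.default_rng(3)
    n = 240
    x1 = rng.uniform(0, 1, n)
    noise_feats = {f"noise{j}": rng.uniform(0, 1, n) for j in range(5)}
    y = 100.0 - 60.0 * x1 + rng.normal(0, 3.0, n)
    return pd.DataFrame({"signal": x1, **noise_feats, "agb": y})


FAST_SPECS = {
    "rf": {"n_estimators": 60, "max_features": 3},
    "xgb": {"n_estimators": 80, "max_depth": 3, "learning_rate": 0.1},
    "gbm": {"n_estimators": 80, "max_depth": 4, "learning_rate": 0.1},
    "svm": {"C": 10.0, "gamma": 0.1},
}
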