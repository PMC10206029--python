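import numpy as np
import pytest

from lhprod.simulate import SyntheticConfig, simulate_trap_dataset


@pytest.fixture(scope="session")
def small_trap():
    """A small literal-mode trap dataset (3 years x 60 days) with truth."""
    cfg = SyntheticConfig(
        n_years=3, subyearling_season=(80, 139), yearling_season=(430, 459),
        mode_days=(100, 115, 130, 440), mode_sds=(8.0, 8.0, 6.0, 10.0),
        trials_per_year=6, seed=3,
    )
    ds, truth = simulate_trap_dataset(cfg, age_class="subyearling")
    return cfg, ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
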