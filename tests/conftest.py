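import numpy as np
import pytest

from ceatrial.config import GeneratorConfig
from ceatrial.simulate import generate_trial
from ceatrial.valuesets import load_value_set


@pytest.fixture(scope="session")
def toy_set():
    return load_value_set("toy")


@pytest.fixture(scope="session")
def au_set():
    """Synthetic additive set spanning exactly [-0.676, 1]."""
    return load_value_set("synthetic-au-range")


@pytest.fixture(scope="session")
def default_dataset(au_set):
    """One full-size simulated trial (1,044 patients, 20 practices)."""
    return generate_trial(GeneratorConfig(seed=1), au_set)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A reduced trial (8 practices, ~180 patients) for fast unit tests."""
    cfg = GeneratorConfig(
        n_practices=8,
        cohort_sizes={"child": 10, "adult": 60, "older": 110},
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture
def small_dataset(au_set):
    return generate_trial(small_config(seed=3), au_set)


def null_irr() -> dict[str, float]:
    return {k: 1.0 for k in ("ed", "adm", "nights", "spec", "pharm")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
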