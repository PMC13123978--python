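import numpy as np
import pytest
from hypothesis import settings

from capspec.synthetic import PlantedSpec, SimConfig, simulate_study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study():
    """A small six-level study with one planted RBP, confounder and copy."""
    cfg = SimConfig(
        n_isolates=80,
        n_sc=8,
        n_kloci=3,
        k_switch_rate=0.1,
        n_background_clusters=30,
        planted_specs=(
            PlantedSpec(target_klocus="KL1", sensitivity=0.95, fpr=0.01, kind="true_rbp"),
            PlantedSpec(target_klocus="KL1", kind="lineage_confounder"),
            PlantedSpec(target_klocus="KL1", kind="correlated_copy", copy_noise=0.02),
        ),
    )
    return simulate_study(cfg, seed=2, companions=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
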