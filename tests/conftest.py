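import numpy as np
import pytest

from rcikit.design import DesignConfig, build_paired_design, build_single_design
from rcikit.simulate import TrueParams, default_true_params, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def strict_config() -> DesignConfig:
    return DesignConfig(mode="strict_formula")


@pytest.fixture
def sp_soil_arvense_pots(default_config):
    """Single + paired pots for one species in SP soil (paper-sized cell)."""
    pots = build_single_design("SP", default_config) + build_paired_design("SP", default_config)
    return [p for p in pots if p.species == "arvense"]


@pytest.fixture
def sp_soil_params() -> TrueParams:
    """Known-truth parameters covering the SP-soil arvense cell."""
    return TrueParams(
        single_cell_means_log={("arvense", "SP", "NZ"): -3.3, ("arvense", "SP", "SP"): -3.5},
        true_rci={("arvense", "SP", "NZ", "SP"): 0.35, ("arvense", "SP", "SP", "NZ"): 0.15},
        beta_nod=0.08,
        sigma_site=0.10,
        sigma_resid=0.30,
        seed=42,
    )


@pytest.fixture
def sp_soil_records(sp_soil_arvense_pots, sp_soil_params):
    return generate_dataset(sp_soil_arvense_pots, sp_soil_params)


@pytest.fixture
def full_records():
    """Noise-bearing records for the entire harvest-consistent study."""
    pots = []
    cfg = DesignConfig()
    for soil in ("NZ", "SP", "UK"):
        pots += build_single_design(soil, cfg) + build_paired_design(soil, cfg)
    return generate_dataset(pots, default_true_params(seed=7, mortality_rate=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
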