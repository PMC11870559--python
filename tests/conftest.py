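import numpy as np
import pytest

from nkact.agents import (ExhaustionParams, MotilityParams, NKKillParams,
                          NKProliferationParams, PhenotypeRates,
                          ProductParams, TumorParams)
from nkact.engine import GridConfig, SimulationConfig
from nkact.fixtures import FixtureSpec, synth_effect_table, synth_expression_pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(n_genes=20, n_cells=50, seed=7)


@pytest.fixture(scope="session")
def effect_table(fixture_spec):
    return synth_effect_table(fixture_spec)


@pytest.fixture(scope="session")
def expression_pool(fixture_spec):
    return synth_expression_pool(fixture_spec)


@pytest.fixture
def static_product():
    """Product with all autonomous dynamics disabled (deterministic board)."""
    def make(**overrides):
        base = dict(
            kill=NKKillParams(mu_c=0.5, sigma_c=0.0, gamma=1.0),
            proliferation=NKProliferationParams(pc=0.0, sigma_pc=0.0),
            exhaustion=ExhaustionParams(s0=5),
            rates=PhenotypeRates(d_c=0.0, d_v=0.0, d_e=0.0, p_v=0.0),
            motility=MotilityParams(m_n=0.0),
        )
        base.update(overrides)
        return ProductParams(**base)
    return make


@pytest.fixture
def tumor_only_growth_config():
    """Sparse tumor-only configuration for growth-rate assays."""
    def make(p_b=0.455, duration_days=6.0, n_init=1000, replicates=5,
             width=100, height=100):
        return SimulationConfig(
            grid=GridConfig(width=width, height=height),
            duration_days=duration_days, n_tumor_init=n_init, products={},
            tumor=TumorParams(p_b=p_b), placement="uniform",
            nk_at_start=False, replicates=replicates)
    return make
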