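import numpy as np
import pytest

import setrvat as sv


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one effect trait, one binary trait and one null
    trait, shared across fast unit tests."""
    cfg = sv.SimulationConfig(
        n_individuals=800,
        n_genes=20,
        variants_per_gene=40,
        traits=(
            sv.TraitConfig(name="quant", seed_genes=(0, 1, 2),
                           variance_fraction=0.4),
            sv.TraitConfig(name="disease", kind="binary", seed_genes=(3, 4),
                           prevalence=0.2, variance_fraction=0.3),
            sv.TraitConfig(name="null", covariate_effect_sd=0.0),
        ),
        rng_seed=1234,
    )
    dataset, truth = sv.simulate_cohort(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240926)
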